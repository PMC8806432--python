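"""Co-expression screen, moderated-t DE, and BH adjustment."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from pairsig import ExpressionMatrix, differential_expression, screen_irlncrnas
from conftest import bf_bh


def _expr(lnc_rows, imm_rows, n_tumor=None, lnc_ids=None, imm_ids=None):
    lnc_ids = lnc_ids or [f"L{i}" for i in range(len(lnc_rows))]
    imm_ids = imm_ids or [f"M{i}" for i in range(len(imm_rows))]
    vals = pd.DataFrame(lnc_rows + imm_rows, index=lnc_ids + imm_ids, dtype=float)
    vals.columns = [f"s{i}" for i in range(vals.shape[1])]
    n = vals.shape[1]
    n_tumor = n if n_tumor is None else n_tumor
    groups = pd.Series(["tumor"] * n_tumor + ["normal"] * (n - n_tumor),
                       index=vals.columns, name="group")
    meta = pd.DataFrame(
        {"biotype": ["lncRNA"] * len(lnc_ids) + ["mRNA"] * len(imm_ids),
         "immune_flag": [False] * len(lnc_ids) + [True] * len(imm_ids)},
        index=vals.index,
    )
    return ExpressionMatrix(values=vals, sample_group=groups, gene_meta=meta)


def test_perfect_linear_dependence_retained():
    imm = [1.0, 2.0, 3.0, 4.0, 5.0]
    expr = _expr([[2 * v for v in imm]], [imm])
    out = screen_irlncrnas(expr, 0.4, 0.001, log2=False)
    assert list(out["lncRNA"]) == ["L0"]
    assert out["r"].iloc[0] == pytest.approx(1.0)
    assert out["best_partner"].iloc[0] == "M0"


def test_r08_with_large_p_not_retained():
    # r = 0.8 over 5 samples: t = 0.8*sqrt(3)/0.6, two-sided p ~ 0.104 >= 0.001
    expr = _expr([[1, 3, 2, 5, 4]], [[1, 2, 3, 4, 5]])
    out = screen_irlncrnas(expr, 0.4, 0.001, log2=False)
    assert out.empty
    relaxed = screen_irlncrnas(expr, 0.4, 0.2, log2=False)
    assert relaxed["r"].iloc[0] == pytest.approx(0.8)
    assert relaxed["p"].iloc[0] == pytest.approx(0.10404, abs=1e-4)


def test_constant_lncrna_skipped():
    expr = _expr([[2, 2, 2, 2], [1, 2, 3, 4]], [[1, 2, 3, 4]])
    out = screen_irlncrnas(expr, 0.4, 0.05, log2=False)
    assert "L0" not in set(out["lncRNA"])
    assert "L1" in set(out["lncRNA"])


def test_retention_invariant_to_sample_order(small_cohort):
    expr, _, _ = small_cohort
    out1 = screen_irlncrnas(expr, 0.4, 0.001)
    rng = np.random.default_rng(0)
    perm = rng.permutation(expr.values.columns)
    shuffled = ExpressionMatrix(
        values=expr.values[perm], sample_group=expr.sample_group,
        gene_meta=expr.gene_meta,
    )
    out2 = screen_irlncrnas(shuffled, 0.4, 0.001)
    assert set(out1["lncRNA"]) == set(out2["lncRNA"])


def test_planted_irlncrnas_recovered(small_cohort, small_spec):
    expr, _, truth = small_cohort
    out = screen_irlncrnas(expr, 0.4, 0.001)
    found = set(out["lncRNA"])
    sens = len(found & set(truth["irlncRNAs"])) / small_spec.n_irlnc
    assert sens >= 0.9


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

def _de_expr(tumor_shift, n=50, sd=0.5, seed=0):
    rng = np.random.default_rng(seed)
    null_t = rng.normal(5, sd, n)
    null_n = rng.normal(5, sd, n)
    sig_t = rng.normal(5 + tumor_shift, sd, n)
    sig_n = rng.normal(5, sd, n)
    raw = np.exp2(np.vstack([np.concatenate([null_t, null_n]),
                             np.concatenate([sig_t, sig_n])])) - 1
    raw = np.clip(raw, 0, None)
    vals = pd.DataFrame(raw, index=["null_gene", "shift_gene"],
                        columns=[f"s{i}" for i in range(2 * n)])
    groups = pd.Series(["tumor"] * n + ["normal"] * n, index=vals.columns, name="group")
    meta = pd.DataFrame({"biotype": ["lncRNA", "lncRNA"],
                         "immune_flag": [False, False]}, index=vals.index)
    return ExpressionMatrix(values=vals, sample_group=groups, gene_meta=meta)


def test_null_gene_not_retained_and_shifted_gene_up():
    expr = _de_expr(tumor_shift=3.0)
    out = differential_expression(expr, ["null_gene", "shift_gene"], 0.05, 1.5)
    assert list(out["lncRNA"]) == ["shift_gene"]
    assert out["direction"].iloc[0] == "up"
    allr = differential_expression(expr, ["null_gene", "shift_gene"], 0.05, 1.5,
                                   return_all=True)
    null_row = allr.set_index("lncRNA").loc["null_gene"]
    assert abs(null_row["log2FC"]) < 0.5


def test_group_with_single_sample_errors(tiny_expr):
    import pandas as pd

    groups = tiny_expr.sample_group.copy()
    groups[:] = ["tumor", "tumor", "tumor", "normal"]
    expr = ExpressionMatrix(values=tiny_expr.values, sample_group=groups,
                            gene_meta=tiny_expr.gene_meta)
    with pytest.raises(ValueError, match=">=2 samples"):
        differential_expression(expr, ["A", "B"], 0.05, 1.5)


def test_bh_small_example():
    _, fdr, _, _ = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")
    assert np.allclose(fdr, [0.04, 0.04, 0.04, 0.04])
    assert np.allclose(bf_bh([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1), st.integers(1, 1000))
def test_bh_matches_stepup_definition(seed, n):
    p = np.random.default_rng(seed).uniform(size=n)
    _, fdr, _, _ = multipletests(p, method="fdr_bh")
    assert np.allclose(fdr, bf_bh(p), atol=1e-12)


def test_de_sensitivity_specificity_on_synthetic(small_cohort, small_spec):
    expr, _, truth = small_cohort
    irlnc = list(truth["irlncRNAs"])
    out = differential_expression(expr, irlnc, 0.05, 1.5)
    found = set(out["lncRNA"])
    true_de = set(truth["de_genes"])
    sens = len(found & true_de) / len(true_de)
    nulls = set(irlnc) - true_de
    spec = len(nulls - found) / len(nulls)
    assert sens >= 0.9 and spec >= 0.9


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not available")
def test_moderated_t_matches_limma_oracle(tmp_path):
    """Cross-check empirical-Bayes moderated p-values against limma."""
    rng = np.random.default_rng(11)
    n_genes, n = 60, 8
    log_t = rng.normal(5, 1.0, (n_genes, n)) * rng.uniform(0.5, 1.5, (n_genes, 1))
    log_n = rng.normal(5, 1.0, (n_genes, n)) * rng.uniform(0.5, 1.5, (n_genes, 1))
    log_t[:5] += 2.0
    logmat = np.hstack([log_t, log_n])
    raw = np.clip(np.exp2(logmat) - 1, 0, None)
    genes = [f"g{i}" for i in range(n_genes)]
    vals = pd.DataFrame(raw, index=genes, columns=[f"s{i}" for i in range(2 * n)])
    groups = pd.Series(["tumor"] * n + ["normal"] * n, index=vals.columns, name="group")
    meta = pd.DataFrame({"biotype": "lncRNA", "immune_flag": False}, index=genes)
    expr = ExpressionMatrix(values=vals, sample_group=groups, gene_meta=meta)
    mine = differential_expression(expr, genes, 0.05, 0.0, return_all=True)

    mat_path = tmp_path / "log.tsv"
    pd.DataFrame(logmat, index=genes).to_csv(mat_path, sep="\t")
    script = tmp_path / "limma.R"
    script.write_text(textwrap.dedent(f"""
        suppressMessages(library(limma))
        m <- as.matrix(read.delim("{mat_path}", row.names=1))
        design <- cbind(Intercept=1, tumor=c(rep(1,{n}), rep(0,{n})))
        fit <- eBayes(lmFit(m, design))
        tab <- topTable(fit, coef="tumor", number=Inf, sort.by="none")
        write.table(tab, "{tmp_path}/limma_out.tsv", sep="\\t", quote=FALSE)
    """))
    subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
    limma = pd.read_csv(tmp_path / "limma_out.tsv", sep="\t")
    mine = mine.set_index("lncRNA").loc[genes]
    assert np.allclose(mine["log2FC"], limma["logFC"], atol=1e-8)
    assert np.allclose(mine["p"], limma["P.Value"], rtol=1e-3)
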