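"""Domain containers and TSV I/O shared by all pipeline stages.

Expression travels as a genes x samples :class:`pandas.DataFrame` wrapped
with sample group labels (tumor/normal) and per-gene metadata (biotype,
immune flag); survival/clinical data as a per-patient DataFrame. All
tables are read and written as UTF-8 TSV with a header row so every stage
can be run and inspected in isolation.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

TUMOR = "tumor"
NORMAL = "normal"

SURV_COLUMNS = ["patient_id", "time", "event", "age", "gender", "grade", "stage"]


class ValidationError(ValueError):
    """Raised when an input table violates a container invariant."""


def _check_unique(ids, what: str) -> None:
    s = pd.Index(ids)
    if s.has_duplicates:
        dups = sorted(s[s.duplicated()].unique().tolist())
        raise ValidationError(f"duplicate {what} id(s): {', '.join(map(str, dups))}")


@dataclasses.dataclass
class ExpressionMatrix:
    """Non-negative expression values (genes x samples) with annotations.

    Attributes
    ----------
    values : DataFrame, index = gene ids, columns = sample ids. Raw scale.
    sample_group : Series mapping sample id -> {"tumor", "normal"}.
    gene_meta : DataFrame indexed by gene id with columns ``biotype``
        ("mRNA" or "lncRNA") and ``immune_flag`` (bool; meaningful for
        mRNAs, which is where immune-gene annotation lives).
    """

    values: pd.DataFrame
    sample_group: pd.Series
    gene_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        _check_unique(self.values.index, "gene")
        _check_unique(self.values.columns, "sample")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            bad = self.values.map(lambda v: not isinstance(v, (int, float, np.number)))
            r, c = np.argwhere(bad.to_numpy())[0]
            raise ValidationError(
                f"non-numeric value at gene {self.values.index[r]!r}, "
                f"sample {self.values.columns[c]!r}"
            )
        if not np.all(np.isfinite(arr)):
            r, c = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite value at gene {self.values.index[r]!r}, "
                f"sample {self.values.columns[c]!r}"
            )
        if (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative value {arr[r, c]} at gene {self.values.index[r]!r}, "
                f"sample {self.values.columns[c]!r}"
            )
        missing = self.values.columns.difference(self.sample_group.index)
        if len(missing):
            raise ValidationError(f"samples without group label: {list(missing)}")
        bad_groups = set(self.sample_group.loc[self.values.columns]) - {TUMOR, NORMAL}
        if bad_groups:
            raise ValidationError(f"unknown sample group label(s): {sorted(bad_groups)}")
        missing_g = self.values.index.difference(self.gene_meta.index)
        if len(missing_g):
            raise ValidationError(f"genes without metadata: {list(missing_g)[:5]}")
        bad_bt = set(self.gene_meta.loc[self.values.index, "biotype"]) - {"mRNA", "lncRNA"}
        if bad_bt:
            raise ValidationError(f"unknown biotype(s): {sorted(bad_bt)}")

    # ---- convenience views -------------------------------------------------
    @property
    def gene_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list:
        mask = self.sample_group.loc[self.values.columns] == group
        return list(self.values.columns[mask.to_numpy()])

    @property
    def tumor_samples(self) -> list:
        return self.samples_in_group(TUMOR)

    @property
    def normal_samples(self) -> list:
        return self.samples_in_group(NORMAL)

    def genes_of_biotype(self, biotype: str) -> list:
        meta = self.gene_meta.loc[self.values.index]
        return list(self.values.index[(meta["biotype"] == biotype).to_numpy()])

    @property
    def lncrna_ids(self) -> list:
        return self.genes_of_biotype("lncRNA")

    @property
    def immune_gene_ids(self) -> list:
        meta = self.gene_meta.loc[self.values.index]
        mask = (meta["biotype"] == "mRNA") & meta["immune_flag"].astype(bool)
        return list(self.values.index[mask.to_numpy()])

    def log2_values(self) -> pd.DataFrame:
        """log2(x + 1) view of the raw values."""
        return np.log2(self.values + 1.0)

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=self.values.loc[list(gene_ids)],
            sample_group=self.sample_group,
            gene_meta=self.gene_meta,
        )

    # ---- I/O ---------------------------------------------------------------
    def write(self, expr_path, groups_path, meta_path) -> None:
        self.values.to_csv(expr_path, sep="\t", index_label="gene_id")
        self.sample_group.rename("group").to_frame().to_csv(
            groups_path, sep="\t", index_label="sample_id"
        )
        self.gene_meta.to_csv(meta_path, sep="\t", index_label="gene_id")


def read_expression(expr_path, groups_path, meta_path) -> ExpressionMatrix:
    """Read an expression TSV (first column gene ids, header = sample ids)
    plus its companion sample-group and gene-metadata TSVs.

    Raises :class:`ValidationError` on duplicate ids or negative /
    non-numeric values, naming the offending gene and sample.
    """
    values = pd.read_csv(expr_path, sep="\t", index_col=0)
    values.index.name = "gene_id"
    groups = pd.read_csv(groups_path, sep="\t", index_col=0)["group"]
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    if "immune_flag" in meta:
        meta["immune_flag"] = meta["immune_flag"].astype(bool)
    return ExpressionMatrix(values=values, sample_group=groups, gene_meta=meta)


# ---------------------------------------------------------------------------
# survival / clinical table
# ---------------------------------------------------------------------------

def validate_survival(surv: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise a clinical table (one row per patient)."""
    missing = [c for c in ("patient_id", "time", "event") if c not in surv.columns]
    if missing:
        raise ValidationError(f"survival table missing column(s): {missing}")
    surv = surv.copy()
    surv["time"] = surv["time"].astype(float)
    surv["event"] = surv["event"].astype(int)
    if not set(surv["event"].unique()) <= {0, 1}:
        raise ValidationError("event indicator must be 0/1")
    if (surv["time"] <= 0).any():
        raise ValidationError("follow-up times must be positive")
    return surv


def read_survival(path) -> pd.DataFrame:
    return validate_survival(pd.read_csv(path, sep="\t"))


def write_survival(surv: pd.DataFrame, path) -> None:
    surv.to_csv(path, sep="\t", index=False)


def filter_patients(surv: pd.DataFrame, min_followup_days: float = 30.0) -> pd.DataFrame:
    """Apply the cohort inclusion rules.

    Patients with follow-up of no more than ``min_followup_days`` days
    (time <= bound, inclusive) are excluded, and duplicated patient ids are
    collapsed to their first occurrence in file order. Idempotent.
    """
    surv = validate_survival(surv)
    n0 = len(surv)
    deduped = surv.drop_duplicates(subset="patient_id", keep="first")
    kept = deduped[deduped["time"] > min_followup_days].reset_index(drop=True)
    if kept.empty:
        raise ValidationError(
            f"no patients remain after the {min_followup_days}-day follow-up filter"
        )
    log.info(
        "filter_patients: %d -> %d (%d duplicates, %d short follow-up)",
        n0, len(kept), n0 - len(deduped), len(deduped) - len(kept),
    )
    return kept
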