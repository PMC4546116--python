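"""Differential-expression stage for the kidney radiotoxicity study.

Implements the transcriptomics criteria used throughout the pipeline: log2
intensities, quantile normalization across samples, a cross-sample variance
filter, per-group Welch t statistics against age-matched controls,
Benjamini-Hochberg FDR adjustment, and the dual significance rule
(q < 0.01 and |log2 ratio| > 0.58, i.e. fold change > 1.5).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: Default dual significance thresholds.
Q_MAX_DEFAULT = 0.01
LFC_MIN_DEFAULT = 0.58  # == log2(1.5) to two decimals

META_COLUMNS = ["sample_id", "tissue", "timepoint_months", "activity_MBq", "replicate"]


class PairingError(ValueError):
    """An exposure group has no age-matched control at its timepoint/tissue."""


@dataclass
class ExpressionSet:
    """Genes x samples matrix of log2 intensities with sample annotations.

    ``sample_meta`` must carry one row per matrix column with columns
    ``sample_id, tissue, timepoint_months, activity_MBq, replicate``;
    controls are the rows with ``activity_MBq == 0``.
    """

    gene_ids: list[str]
    matrix: np.ndarray
    sample_meta: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.gene_ids = list(self.gene_ids)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene identifiers")
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (genes x samples)")
        if self.matrix.shape != (len(self.gene_ids), len(self.sample_meta)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_meta)} samples"
            )
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("matrix contains non-finite values")
        missing = [c for c in META_COLUMNS if c not in self.sample_meta.columns]
        if missing:
            raise ValueError(f"sample_meta missing columns: {missing}")
        # every exposure sample needs an age-matched control set
        meta = self.sample_meta
        ctrl = meta[meta["activity_MBq"] == 0]
        for (tissue, tp), _ in meta[meta["activity_MBq"] > 0].groupby(
            ["tissue", "timepoint_months"]
        ):
            hit = ctrl[(ctrl["tissue"] == tissue) & (ctrl["timepoint_months"] == tp)]
            if hit.empty:
                raise PairingError(
                    f"no control samples for tissue={tissue!r}, timepoint={tp}"
                )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    def subset_genes(self, keep: np.ndarray) -> "ExpressionSet":
        genes = [g for g, k in zip(self.gene_ids, keep) if k]
        return ExpressionSet(genes, self.matrix[np.asarray(keep, bool)], self.sample_meta)

    # -- TSV + JSON sidecar round trip ------------------------------------
    def to_tsv(self, tsv_path: str | Path, meta_path: str | Path) -> None:
        df = pd.DataFrame(
            self.matrix, index=self.gene_ids, columns=self.sample_meta["sample_id"]
        )
        df.index.name = "gene"
        df.to_csv(tsv_path, sep="\t")
        Path(meta_path).write_text(
            json.dumps(self.sample_meta.to_dict(orient="records"), indent=1)
        )

    @classmethod
    def from_tsv(cls, tsv_path: str | Path, meta_path: str | Path) -> "ExpressionSet":
        df = pd.read_csv(tsv_path, sep="\t", index_col=0)
        meta = pd.DataFrame(json.loads(Path(meta_path).read_text()))
        meta = meta.set_index("sample_id", drop=False).loc[df.columns].reset_index(drop=True)
        return cls(list(df.index), df.to_numpy(), meta)


# ---------------------------------------------------------------------------
# preprocessing


def quantile_normalize(matrix: np.ndarray) -> np.ndarray:
    """Quantile-normalize columns (samples) of a genes x samples matrix.

    Each sample's sorted values are replaced by the across-sample mean of the
    order statistics; tied values within a sample receive the mean of the
    reference values over their tied rank range.
    """
    x = np.asarray(matrix, dtype=float)
    order = np.argsort(x, axis=0, kind="mergesort")
    ref = np.mean(np.take_along_axis(x, order, axis=0), axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        ranks = np.empty(len(col), dtype=int)
        ranks[order[:, j]] = np.arange(len(col))
        vals = ref[ranks]
        # average reference values over tied ranks
        s = pd.Series(vals).groupby(pd.Series(col)).transform("mean")
        out[:, j] = s.to_numpy()
    return out


def preprocess(es: ExpressionSet, variance_quantile: float = 0.2) -> ExpressionSet:
    """Quantile-normalize, then drop the lowest-variance genes.

    ``variance_quantile`` is the fraction of genes removed from the bottom of
    the cross-sample variance distribution; 0 disables the filter.
    """
    if es.n_samples < 2:
        raise ValueError("preprocess requires at least 2 samples")
    if not 0 <= variance_quantile < 1:
        raise ValueError("variance_quantile must be in [0, 1)")
    norm = quantile_normalize(es.matrix)
    es = ExpressionSet(es.gene_ids, norm, es.sample_meta)
    if variance_quantile == 0:
        return es
    variances = es.matrix.var(axis=1, ddof=1)
    threshold = np.quantile(variances, variance_quantile)
    keep = variances > threshold
    if not keep.any():
        warnings.warn("variance filter removed every gene", stacklevel=2)
    return es.subset_genes(keep)


# ---------------------------------------------------------------------------
# statistics


def welch_t(group: np.ndarray, control: np.ndarray) -> tuple[float, float]:
    """Two-sided Welch t-test; zero-variance-in-both resolved by mean equality."""
    group = np.asarray(group, float)
    control = np.asarray(control, float)
    if group.var(ddof=1) == 0 and control.var(ddof=1) == 0:
        equal = np.isclose(group.mean(), control.mean())
        return (0.0, 1.0) if equal else (np.inf * np.sign(group.mean() - control.mean()), 0.0)
    with warnings.catch_warnings():
        # near-identical replicates trip scipy's precision warning; the
        # zero-variance case is resolved above
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(group, control, equal_var=False)
    return float(t), float(p)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order-preserving, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_table(
    es: ExpressionSet,
    tissue: str,
    timepoint_months: float,
    activity_MBq: float,
    q_max: float = Q_MAX_DEFAULT,
    lfc_min: float = LFC_MIN_DEFAULT,
) -> pd.DataFrame:
    """Per-gene differential expression of one exposure group vs its control.

    Returns a DataFrame with columns gene, log2_ratio, p, q, significant,
    direction; BH adjustment is applied across genes within this group.
    """
    meta = es.sample_meta
    sel_g = (
        (meta["tissue"] == tissue)
        & (meta["timepoint_months"] == timepoint_months)
        & (meta["activity_MBq"] == activity_MBq)
    )
    sel_c = (
        (meta["tissue"] == tissue)
        & (meta["timepoint_months"] == timepoint_months)
        & (meta["activity_MBq"] == 0)
    )
    if sel_g.sum() < 2 or sel_c.sum() < 2:
        raise PairingError(
            f"group ({tissue}, {timepoint_months} mo, {activity_MBq} MBq) needs "
            f">= 2 exposed and >= 2 control replicates "
            f"(found {int(sel_g.sum())}/{int(sel_c.sum())})"
        )
    g = es.matrix[:, sel_g.to_numpy()]
    c = es.matrix[:, sel_c.to_numpy()]
    lfc = g.mean(axis=1) - c.mean(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(g, c, axis=1, equal_var=False)
    t, p = np.asarray(t, float), np.asarray(p, float)
    # both-samples-constant rows: resolved by mean equality (documented
    # convention), not left as NaN
    degenerate = (g.var(axis=1, ddof=1) == 0) & (c.var(axis=1, ddof=1) == 0)
    equal = degenerate & np.isclose(lfc, 0.0)
    shifted = degenerate & ~equal
    p[shifted] = 0.0
    t[shifted] = np.sign(lfc[shifted]) * np.inf
    p[equal], t[equal] = 1.0, 0.0
    out = pd.DataFrame({"gene": es.gene_ids, "log2_ratio": lfc, "p": p, "t": t})
    out["q"] = bh_adjust(out["p"].to_numpy())
    return call_significant(out, q_max=q_max, lfc_min=lfc_min)


def call_significant(
    de: pd.DataFrame, q_max: float = Q_MAX_DEFAULT, lfc_min: float = LFC_MIN_DEFAULT
) -> pd.DataFrame:
    """Apply the dual threshold: q < q_max AND |log2_ratio| > lfc_min (strict)."""
    de = de.copy()
    de["significant"] = (de["q"] < q_max) & (de["log2_ratio"].abs() > lfc_min)
    de["direction"] = np.where(de["log2_ratio"] > 0, "up", "down")
    de.loc[~de["significant"], "direction"] = ""
    return de


def de_all_groups(
    es: ExpressionSet,
    q_max: float = Q_MAX_DEFAULT,
    lfc_min: float = LFC_MIN_DEFAULT,
) -> dict[tuple[str, float, float], pd.DataFrame]:
    """Run :func:`de_table` for every (tissue, timepoint, activity) group."""
    meta = es.sample_meta
    groups = (
        meta[meta["activity_MBq"] > 0][["tissue", "timepoint_months", "activity_MBq"]]
        .drop_duplicates()
        .itertuples(index=False)
    )
    return {
        (t, tp, a): de_table(es, t, tp, a, q_max=q_max, lfc_min=lfc_min)
        for t, tp, a in groups
    }
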