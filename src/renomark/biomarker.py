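"""Biomarker identification: recurrence across dose x time groups, overlap
with the packaged marker catalogue, Spearman dose-response scoring, and a
transparent regulator-target overlap/enrichment ranking."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats


class IncompleteDesignError(ValueError):
    """DE results are missing for one or more design groups."""

    def __init__(self, missing):
        self.missing = list(missing)
        super().__init__(f"missing DE results for groups: {self.missing}")


def _norm(symbol: str) -> str:
    return str(symbol).strip().upper()


def _load_fixture(name: str) -> pd.DataFrame:
    with resources.files("renomark.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


# ---------------------------------------------------------------------------
# packaged catalogues


@dataclass
class MarkerCatalogue:
    """Published marker panel: gene categories plus per-group log2 ratios.

    Categories are kidney_injury, kidney_injury_and_radiation, or radiation;
    protein_flag marks genes also proposed as protein-level biodosimeters.
    """

    table: pd.DataFrame = field(repr=False)

    @classmethod
    def load(cls) -> "MarkerCatalogue":
        return cls(table=_load_fixture("table1_markers.tsv"))

    def genes(self, tissue: str | None = None) -> set[str]:
        t = self.table if tissue is None else self.table[self.table["tissue"] == tissue]
        return set(t["gene"])

    def category_of(self, gene: str) -> str | None:
        hit = self.table[self.table["gene"].map(_norm) == _norm(gene)]
        return None if hit.empty else str(hit["category"].iloc[0])

    def panel(self, tissue: str) -> pd.DataFrame:
        """(gene, timepoint, activity) -> log2_ratio rows for one tissue."""
        return self.table[self.table["tissue"] == tissue].reset_index(drop=True)


@dataclass
class RegulatorMap:
    """Upstream regulator -> target gene sets, per tissue."""

    targets: dict[tuple[str, str], frozenset[str]]

    @classmethod
    def load(cls) -> "RegulatorMap":
        df = _load_fixture("table2_regulators.tsv")
        out: dict[tuple[str, str], set[str]] = {}
        for row in df.itertuples(index=False):
            out.setdefault((row.tissue, row.regulator), set()).add(row.target)
        if any(len(v) == 0 for v in out.values()):
            raise ValueError("regulator with empty target set")
        return cls({k: frozenset(v) for k, v in out.items()})

    def regulators(self, tissue: str) -> list[str]:
        return sorted({r for (t, r) in self.targets if t == tissue})

    def targets_of(self, tissue: str, regulator: str) -> frozenset[str]:
        return self.targets.get((tissue, regulator), frozenset())


def load_blood_effect_table() -> pd.DataFrame:
    """Packaged test/control percent table (blood, body, scintigraphy)."""
    return _load_fixture("table3_ratios.tsv")


# ---------------------------------------------------------------------------
# recurrence


@dataclass
class RecurrenceMatrix:
    """Genes x (timepoint, activity) table of log2 ratios where significant.

    One matrix per tissue; cells are NaN where the gene was not called
    significant in that group.
    """

    tissue: str
    table: pd.DataFrame = field(repr=False)  # index genes, columns (tp, act)

    @property
    def n_groups(self) -> int:
        return self.table.shape[1]

    def filled_cells(self) -> int:
        return int(self.table.notna().to_numpy().sum())


def build_recurrence(
    de_results: dict[tuple[str, float, float], pd.DataFrame],
    tissue: str,
    expected_groups: list[tuple[float, float]] | None = None,
) -> RecurrenceMatrix:
    """Assemble the recurrence matrix for one tissue from per-group DE tables.

    ``expected_groups`` lists the (timepoint, activity) cells the design
    requires; a missing cell raises :class:`IncompleteDesignError`.
    """
    groups = {
        (tp, act): df for (t, tp, act), df in de_results.items() if t == tissue
    }
    if expected_groups is None:
        expected_groups = sorted(groups)
    missing = [g for g in expected_groups if g not in groups]
    if missing:
        raise IncompleteDesignError([(tissue, tp, a) for tp, a in missing])
    genes = sorted({g for df in groups.values() for g in df["gene"]})
    cols = pd.MultiIndex.from_tuples(
        sorted(expected_groups), names=["timepoint_months", "activity_MBq"]
    )
    table = pd.DataFrame(np.nan, index=genes, columns=cols)
    for (tp, act) in expected_groups:
        df = groups[(tp, act)]
        sig = df[df["significant"]]
        table.loc[sig["gene"].to_numpy(), (tp, act)] = sig["log2_ratio"].to_numpy()
    return RecurrenceMatrix(tissue=tissue, table=table)


def recurrence_from_catalogue(cat: MarkerCatalogue, tissue: str) -> RecurrenceMatrix:
    """Fixture mode: the published marker panel as a recurrence matrix."""
    panel = cat.panel(tissue)
    tps = sorted(panel["timepoint_months"].unique())
    acts = sorted(panel["activity_MBq"].unique())
    cols = pd.MultiIndex.from_product(
        [tps, acts], names=["timepoint_months", "activity_MBq"]
    )
    genes = sorted(panel["gene"].unique())
    table = pd.DataFrame(np.nan, index=genes, columns=cols)
    for row in panel.itertuples(index=False):
        table.loc[row.gene, (row.timepoint_months, row.activity_MBq)] = row.log2_ratio
    return RecurrenceMatrix(tissue=tissue, table=table)


def recurrence_count(m: RecurrenceMatrix, gene: str) -> int:
    """Number of groups (within the matrix's tissue) where the gene is filled."""
    key = [g for g in m.table.index if _norm(g) == _norm(gene)]
    if not key:
        return 0
    return int(m.table.loc[key[0]].notna().sum())


def marker_overlap(
    m: RecurrenceMatrix, cat: MarkerCatalogue, tissue: str | None = None
) -> tuple[pd.DataFrame, int]:
    """Catalogue genes appearing in any group of the matrix.

    Returns (annotated gene table, unique_count); matching is
    case-insensitive after trimming, counts are per distinct gene.
    """
    tissue = tissue or m.tissue
    cat_rows = (
        cat.table[["gene", "category", "protein_flag"]]
        .drop_duplicates(subset="gene")
        .assign(key=lambda d: d["gene"].map(_norm))
    )
    present = {
        _norm(g)
        for g in m.table.index[m.table.notna().any(axis=1)]
    }
    hits = cat_rows[cat_rows["key"].isin(present)].drop(columns="key")
    hits = hits.sort_values("gene").reset_index(drop=True)
    counts = [
        recurrence_count(m, g) for g in hits["gene"]
    ]
    hits["recurrence_count"] = counts
    return hits, int(len(hits))


# ---------------------------------------------------------------------------
# dose response


@dataclass
class DoseResponse:
    rho: float
    monotone: bool
    n: int

    @property
    def sufficient(self) -> bool:
        return self.n >= 3


def dose_response_score(lfc_by_dose) -> DoseResponse:
    """Spearman rank correlation of log2 ratios against dose order.

    ``lfc_by_dose`` is ordered by increasing dose; missing cells (None/NaN)
    are excluded pairwise. Fewer than 3 values yields an insufficient-data
    result (rho = NaN) rather than an error.
    """
    vals = np.array(
        [np.nan if v is None else float(v) for v in lfc_by_dose], dtype=float
    )
    keep = np.isfinite(vals)
    v = vals[keep]
    if v.size < 3:
        return DoseResponse(rho=float("nan"), monotone=False, n=int(v.size))
    order = np.arange(len(vals))[keep]
    with warnings.catch_warnings():
        # a constant input yields rho = NaN by design
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        rho = stats.spearmanr(order, v).statistic
    monotone = bool(np.all(np.diff(v) > 0))
    return DoseResponse(rho=float(rho), monotone=monotone, n=int(v.size))


# ---------------------------------------------------------------------------
# regulator enrichment


def regulator_enrichment(
    gene_set,
    regmap: RegulatorMap,
    tissue: str,
    universe_size: int,
) -> pd.DataFrame:
    """Overlap and one-sided Fisher exact enrichment per upstream regulator.

    This is a transparent hypergeometric-tail computation over the packaged
    regulator-target map, ranked by (overlap desc, p asc, name). The
    proprietary upstream-regulator scoring of commercial pathway tools is
    deliberately not reproduced.
    """
    regs = regmap.regulators(tissue)
    if not regs:
        raise ValueError(f"no regulators for tissue {tissue!r}")
    genes = {_norm(g) for g in gene_set}
    all_targets = {
        _norm(t) for r in regs for t in regmap.targets_of(tissue, r)
    }
    if universe_size < len(genes | all_targets):
        raise ValueError("universe_size smaller than observed gene universe")
    rows = []
    for reg in regs:
        targets = {_norm(t): t for t in regmap.targets_of(tissue, reg)}
        overlap = sorted(targets[k] for k in targets.keys() & genes)
        k = len(overlap)
        # one-sided Fisher exact == hypergeometric upper tail
        p = float(stats.hypergeom.sf(k - 1, universe_size, len(targets), len(genes)))
        rows.append(
            {
                "regulator": reg,
                "overlap": k,
                "overlap_genes": ",".join(overlap),
                "n_targets": len(targets),
                "p": min(p, 1.0),
            }
        )
    df = pd.DataFrame(rows)
    df = df.sort_values(
        ["overlap", "p", "regulator"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return df
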