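"""Phosphomimetic enrichment scoring and concordance with affinity data.

For each bait x phosphosite, every wild-type peptide covering the site is
paired with its matched single-E phosphomimetic variant across overlapping
peptides and replicate selections.  The phosphomimetic enrichment score
over the n datapoints,

    PES = sum_i nc_i^pm / (nc_i^wt + nc_i^pm) - sum_i nc_i^wt / (nc_i^wt + nc_i^pm),

is bounded by +-n; positive values mean the phosphomimetic is
preferentially enriched (phosphorylation predicted to enable binding),
negative values the converse.  Significance is attached with a two-sided
Mann-Whitney test on the wt vs pm count vectors, and sites are classified
enabling/disabling at |PES| >= 2 and P <= 0.01 by default.

The module also runs the orthogonal concordance analysis against a
validation panel of fluorescence-polarization affinities (wild-type,
glutamate and phospho-peptide K_D values per bait-phosphosite pair).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, spearmanr

from phosdisplay import binding_affinity
from phosdisplay.library_design import (
    PHOSPHOMIMETIC,
    WILD_TYPE,
    DesignError,
    LibraryEntry,
    PhosphositeRecord,
)

ENABLING = "enabling"
DISABLING = "disabling"
NOT_SIGNIFICANT = "not_significant"

DEFAULT_PES_MIN = 2.0
DEFAULT_P_MAX = 0.01
STRINGENT_P_MAX = 0.001


@dataclass
class PairObservations:
    """Matched (nc_wt, nc_pm) normalized counts for one bait x phosphosite."""

    bait_id: str
    protein_ac: str
    position: int
    wt: np.ndarray
    pm: np.ndarray

    def __post_init__(self) -> None:
        self.wt = np.asarray(self.wt, dtype=float)
        self.pm = np.asarray(self.pm, dtype=float)
        if self.wt.shape != self.pm.shape or self.wt.ndim != 1:
            raise ValueError("wt and pm must be matched 1-d vectors")
        if self.n < 1:
            raise ValueError("need at least one datapoint")
        if np.any(self.wt < 0) or np.any(self.pm < 0):
            raise ValueError("counts must be non-negative")
        if np.any(self.wt + self.pm == 0):
            raise ValueError("datapoints with nc_wt = nc_pm = 0 must be excluded")

    @property
    def n(self) -> int:
        return int(self.wt.size)


def build_pair_observations(
    tables_by_replicate: dict[str, "object"],
    design: list[LibraryEntry],
    bait_id: str,
) -> list[PairObservations]:
    """Collect per-phosphosite wt/pm datapoints from merged replicate tables.

    ``tables_by_replicate`` maps replicate id to a day-merged normalized
    :class:`~phosdisplay.selection_processing.SelectionCounts`.  One
    datapoint is produced per covering peptide pair per replicate;
    all-zero datapoints are excluded, and sites for which every datapoint
    is zero yield no observations.
    """
    wt_seqs = {e.peptide_seq for e in design if e.variant == WILD_TYPE}
    by_site: dict[tuple[str, int], list[tuple[str, str]]] = {}
    for e in design:
        if e.variant != PHOSPHOMIMETIC:
            continue
        wt_pep = e.tile.sequence
        if wt_pep not in wt_seqs:
            raise DesignError(
                f"phosphomimetic peptide {e.peptide_seq} has no wild-type "
                "partner in the design"
            )
        key = (e.phosphosite.protein_ac, e.phosphosite.position)
        by_site.setdefault(key, []).append((wt_pep, e.peptide_seq))

    observations = []
    for (ac, pos), pairs in sorted(by_site.items()):
        wt_vals, pm_vals = [], []
        for wt_pep, pm_pep in pairs:
            for _rep, table in sorted(tables_by_replicate.items()):
                nc_wt = table.counts.get(wt_pep, 0.0)
                nc_pm = table.counts.get(pm_pep, 0.0)
                if nc_wt + nc_pm > 0:
                    wt_vals.append(nc_wt)
                    pm_vals.append(nc_pm)
        if wt_vals:
            observations.append(
                PairObservations(bait_id, ac, pos, np.array(wt_vals), np.array(pm_vals))
            )
    return observations


def pes(obs: PairObservations) -> float:
    """Phosphomimetic enrichment score: signed sum of per-datapoint fractions."""
    total = obs.wt + obs.pm
    return float(np.sum((obs.pm - obs.wt) / total))


def mann_whitney_two_sided(wt_counts, pm_counts) -> float:
    """Two-sided Mann-Whitney U p-value comparing wt and pm count vectors.

    Uses the exact null distribution when both groups have <= 10
    observations and there are no ties; otherwise the normal approximation
    with tie and continuity corrections.
    """
    wt = np.asarray(wt_counts, dtype=float)
    pm = np.asarray(pm_counts, dtype=float)
    if wt.size == 0 or pm.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([wt, pm])
    has_ties = np.unique(pooled).size < pooled.size
    if wt.size <= 10 and pm.size <= 10 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = mannwhitneyu(wt, pm, alternative="two-sided", method=method,
                       use_continuity=True)
    return float(res.pvalue)


def classify(
    pes_value: float,
    p_value: float,
    pes_min: float = DEFAULT_PES_MIN,
    p_max: float = DEFAULT_P_MAX,
) -> str:
    if p_value <= p_max and pes_value >= pes_min:
        return ENABLING
    if p_value <= p_max and pes_value <= -pes_min:
        return DISABLING
    return NOT_SIGNIFICANT


def score_phosphosites(
    observations: list[PairObservations],
    pes_min: float = DEFAULT_PES_MIN,
    p_max: float = DEFAULT_P_MAX,
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Score a list of PairObservations into a tidy results table."""
    rows = []
    for obs in observations:
        score = pes(obs)
        p = mann_whitney_two_sided(obs.wt, obs.pm)
        rows.append(
            {
                "bait_id": obs.bait_id,
                "protein_ac": obs.protein_ac,
                "position": obs.position,
                "pes": score,
                "p_value": p,
                "n": obs.n,
                "classification": classify(score, p, pes_min, p_max),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["bait_id", "protein_ac", "position", "pes", "p_value", "n",
                 "classification"],
    )
    if bh_correction and len(df):
        df["p_bh"] = _benjamini_hochberg(df["p_value"].to_numpy())
    return df


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, p[i] * m / (rank_idx + 1))
        adj[i] = running
    return adj


def summarize_modulation(
    results: pd.DataFrame,
    pes_min: float = DEFAULT_PES_MIN,
    p_max: float = DEFAULT_P_MAX,
) -> dict:
    """Count modulated sites in a scored results table at given cutoffs."""
    sig = (results["p_value"] <= p_max) & (results["pes"].abs() >= pes_min)
    enabling = sig & (results["pes"] > 0)
    disabling = sig & (results["pes"] < 0)
    n = len(results)
    return {
        "n_pairs": n,
        "n_modulated": int(sig.sum()),
        "n_enabling": int(enabling.sum()),
        "n_disabling": int(disabling.sum()),
        "fraction_modulated": float(sig.sum() / n) if n else 0.0,
    }


def annotate_regulators(
    results: pd.DataFrame, sites: list[PhosphositeRecord]
) -> tuple[pd.DataFrame, dict]:
    """Join kinase/phosphatase annotations onto scored phosphosites."""
    kin = {(s.protein_ac, s.position): ";".join(s.kinases) for s in sites}
    pho = {(s.protein_ac, s.position): ";".join(s.phosphatases) for s in sites}
    out = results.copy()
    keys = list(zip(out["protein_ac"], out["position"]))
    out["kinases"] = [kin.get(k, "") for k in keys]
    out["phosphatases"] = [pho.get(k, "") for k in keys]
    n = len(out)
    n_kin = int((out["kinases"] != "").sum())
    n_pho = int((out["phosphatases"] != "").sum())
    summary = {
        "n_sites": n,
        "n_with_kinase": n_kin,
        "fraction_with_kinase": n_kin / n if n else 0.0,
        "n_with_phosphatase": n_pho,
        "fraction_with_phosphatase": n_pho / n if n else 0.0,
    }
    return out, summary


# --------------------------------------------------------------------------
# Concordance with orthogonal affinity measurements
# --------------------------------------------------------------------------

def load_validation_table(path=None, representative_only: bool = False) -> pd.DataFrame:
    """Load a validation affinity panel (ships with a 32-triplet FP panel).

    Columns: bait, position_label, peptide, kd_wt, kd_pm, kd_phos (strings
    that may be numeric, a bound "<x", or "n.b."), pes, p_value,
    representative.  ``representative_only`` keeps one row per
    bait-phosphosite pair for baits with multiple binding pockets (the
    pocket the selection probed, e.g. the KPNA4 major pocket).
    """
    if path is None:
        ref = importlib.resources.files("phosdisplay").joinpath(
            "data/validation_affinities.tsv"
        )
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", dtype=str)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
    df["pes"] = df["pes"].astype(float)
    df["p_value"] = df["p_value"].astype(float)
    df["representative"] = df["representative"].astype(int)
    if representative_only:
        df = df[df["representative"] == 1].reset_index(drop=True)
    return df


parse_kd = binding_affinity.parse_kd


def concordance_analysis(
    records: pd.DataFrame,
    fold_min: float = 2.0,
    pes_min: float = DEFAULT_PES_MIN,
    p_max: float = DEFAULT_P_MAX,
) -> dict:
    """Compare PES-based calls with affinity fold changes.

    A record *passes* the screening cutoffs when ``p <= p_max`` and
    ``|pes| >= pes_min``.  A passing record *agrees* when the PES sign
    matches the direction of a >= ``fold_min`` change between the
    wild-type and phosphorylated K_D (enabling = tighter binding of the
    phospho-peptide).  "<x" bounds give a fold of at least kd_wt/x;
    "n.b." counts as a disabling change of at least ``fold_min``.
    """
    verdicts = []
    for _, row in records.iterrows():
        passes = row["p_value"] <= p_max and abs(row["pes"]) >= pes_min
        fold, direction = binding_affinity.fold_change(
            row["kd_wt"], row["kd_phos"], threshold=fold_min
        )
        pes_direction = ENABLING if row["pes"] > 0 else DISABLING
        agrees = passes and direction == pes_direction
        verdicts.append(
            {
                "bait": row["bait"],
                "position_label": row["position_label"],
                "peptide": row.get("peptide", ""),
                "pes": row["pes"],
                "p_value": row["p_value"],
                "affinity_fold": fold,
                "affinity_direction": direction,
                "passes_cutoffs": passes,
                "agrees": agrees,
            }
        )
    vdf = pd.DataFrame(verdicts)
    n_pass = int(vdf["passes_cutoffs"].sum()) if len(vdf) else 0
    n_agree = int(vdf["agrees"].sum()) if len(vdf) else 0
    return {
        "n_records": len(vdf),
        "n_pass": n_pass,
        "n_agree": n_agree,
        "agreement_fraction": n_agree / n_pass if n_pass else float("nan"),
        "verdicts": vdf,
    }


def _finite_log2_folds(records: pd.DataFrame, column: str) -> pd.Series:
    """Signed log2(kd_wt / kd_<column>) where both cells are numeric."""
    out = []
    for _, row in records.iterrows():
        wt, wt_kind = parse_kd(row["kd_wt"])
        var, var_kind = parse_kd(row[column])
        if wt_kind == "numeric" and var_kind == "numeric":
            out.append(np.log2(wt / var))
        else:
            out.append(np.nan)
    return pd.Series(out, index=records.index)


def affinity_fold_correlation(records: pd.DataFrame) -> tuple[float, int]:
    """Spearman correlation of phosphomimetic vs phospho fold changes.

    Correlates signed log2(kd_wt/kd_pm) with log2(kd_wt/kd_phos) over
    records with finite values on both axes.  Returns (rho, n_used).
    """
    x = _finite_log2_folds(records, "kd_pm")
    y = _finite_log2_folds(records, "kd_phos")
    ok = x.notna() & y.notna()
    rho = spearmanr(x[ok], y[ok]).statistic
    return float(rho), int(ok.sum())


def pes_affinity_correlation(records: pd.DataFrame) -> tuple[float, int]:
    """Spearman correlation of PES with the wt-vs-phospho fold change."""
    y = _finite_log2_folds(records, "kd_phos")
    ok = y.notna()
    rho = spearmanr(records.loc[ok, "pes"], y[ok]).statistic
    return float(rho), int(ok.sum())
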