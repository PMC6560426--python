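"""Two-group summaries and hypothesis tests behind the abundance tables.

The t-test is the pooled-variance Student form (GraphPad's "unpaired t test"
default), computable either from raw per-sample values or from printed
group summaries (mean, SEM, n).  P-values are reported unadjusted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config_and_io import PipelineConfig
from .diversity_ordination import alpha_table

__all__ = [
    "GroupComparison",
    "CorrelationResult",
    "select_main_otus",
    "ttest_from_summary",
    "ttest_from_raw",
    "welch_from_raw",
    "pearson",
    "fold_change",
    "build_report",
]


@dataclass(frozen=True)
class GroupComparison:
    feature_id: str
    mean_a: float
    sem_a: float
    n_a: int
    mean_b: float
    sem_b: float
    n_b: int
    t_stat: float
    df: int
    p_value: float
    fold_change: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.df != self.n_a + self.n_b - 2:
            raise ValueError("df must equal n_a + n_b - 2")
        if not (0.0 < self.p_value <= 1.0) and not self.degenerate:
            raise ValueError("p-value must lie in (0, 1]")
        if self.sem_a < 0 or self.sem_b < 0:
            raise ValueError("SEMs must be non-negative")


@dataclass(frozen=True)
class CorrelationResult:
    otu_id: str
    covariate: str
    r: float
    n: int
    p_value: float

    def __post_init__(self) -> None:
        if not (-1.0 - 1e-12 <= self.r <= 1.0 + 1e-12):
            raise ValueError("r must lie in [-1, 1]")


def select_main_otus(
    rel_abund: pd.DataFrame,
    groups: Mapping[str, Sequence[str]],
    threshold_pct: float = 1.0,
) -> list[str]:
    """OTUs whose mean percent relative abundance reaches ``threshold_pct``
    (inclusive) in at least one group.

    ``rel_abund`` is OTUs x samples in percent; ``groups`` maps group label
    to its sample ids.
    """
    if len(groups) != 2:
        raise ValueError("exactly two groups are required")
    keep = []
    for otu in rel_abund.index:
        for samples in groups.values():
            if rel_abund.loc[otu, list(samples)].mean() >= threshold_pct:
                keep.append(otu)
                break
    return keep


def ttest_from_summary(
    mean_a: float, sem_a: float, n_a: int,
    mean_b: float, sem_b: float, n_b: int,
    feature_id: str = "",
) -> GroupComparison:
    """Pooled-variance Student t-test from printed group summaries.

    SDs are recovered as SEM * sqrt(n); the two-sided p comes from the t
    distribution with n_a + n_b - 2 degrees of freedom.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs n >= 2")
    if sem_a < 0 or sem_b < 0:
        raise ValueError("SEMs must be non-negative")
    df = n_a + n_b - 2
    var_a = (sem_a * math.sqrt(n_a)) ** 2
    var_b = (sem_b * math.sqrt(n_b)) ** 2
    pooled = ((n_a - 1) * var_a + (n_b - 1) * var_b) / df
    se_diff = math.sqrt(pooled * (1.0 / n_a + 1.0 / n_b))
    degenerate = False
    if se_diff == 0.0:
        if mean_a == mean_b:
            t_stat, p_value = 0.0, 1.0
        else:  # zero spread but different means: p -> 0, flagged
            t_stat = math.inf if mean_a > mean_b else -math.inf
            p_value = 0.0
            degenerate = True
    else:
        t_stat = (mean_a - mean_b) / se_diff
        p_value = float(2.0 * sps.t.sf(abs(t_stat), df))
        p_value = max(p_value, np.nextafter(0.0, 1.0))
    return GroupComparison(
        feature_id=feature_id,
        mean_a=mean_a, sem_a=sem_a, n_a=n_a,
        mean_b=mean_b, sem_b=sem_b, n_b=n_b,
        t_stat=t_stat, df=df, p_value=p_value,
        fold_change=fold_change(mean_a, mean_b) if mean_b > 0 else math.inf,
        degenerate=degenerate,
    )


def _summaries(values: Sequence[float]) -> tuple[float, float, int]:
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("each group needs at least 2 values")
    return float(arr.mean()), float(arr.std(ddof=1) / math.sqrt(arr.size)), arr.size


def ttest_from_raw(
    values_a: Sequence[float], values_b: Sequence[float], feature_id: str = ""
) -> GroupComparison:
    """Pooled t-test on raw values; identical to the summary form applied to
    the groups' own means and SEMs."""
    mean_a, sem_a, n_a = _summaries(values_a)
    mean_b, sem_b, n_b = _summaries(values_b)
    return ttest_from_summary(mean_a, sem_a, n_a, mean_b, sem_b, n_b, feature_id)


def welch_from_raw(
    values_a: Sequence[float], values_b: Sequence[float]
) -> tuple[float, float]:
    """Welch's unequal-variance alternative (t, p); not the default."""
    t_stat, p_value = sps.ttest_ind(values_a, values_b, equal_var=False)
    return float(t_stat), float(p_value)


def pearson(x: Sequence[float], y: Sequence[float],
            otu_id: str = "", covariate: str = "") -> CorrelationResult:
    """Product-moment correlation; two-sided p from t = r sqrt(n-2)/sqrt(1-r^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("pearson requires n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = np.nextafter(0.0, 1.0)
    else:
        t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
        p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return CorrelationResult(otu_id=otu_id, covariate=covariate, r=r, n=n, p_value=p)


def fold_change(mean_a: float, mean_b: float) -> float:
    """Ratio of group means; display convention is one decimal place."""
    if mean_b == 0:
        return math.inf
    return mean_a / mean_b


def _group_row(feature: str, vec: pd.Series,
               groups: Mapping[str, Sequence[str]]) -> dict:
    (label_a, samples_a), (label_b, samples_b) = groups.items()
    comp = ttest_from_raw(
        vec[list(samples_a)].to_numpy(), vec[list(samples_b)].to_numpy(), feature
    )
    return {
        "feature": feature,
        f"mean_{label_a}": comp.mean_a, f"sem_{label_a}": comp.sem_a,
        f"mean_{label_b}": comp.mean_b, f"sem_{label_b}": comp.sem_b,
        "p_value": comp.p_value, "fold_change": comp.fold_change,
    }


def build_report(
    rel_abund: pd.DataFrame,
    assignments: Mapping[str, object],
    metadata: pd.DataFrame,
    cfg: PipelineConfig | None = None,
    counts: pd.DataFrame | None = None,
    group_col: str = "treatment",
    outdir: str | None = None,
) -> dict[str, pd.DataFrame]:
    """Assemble the group-comparison report tables.

    Returns (and optionally writes as TSV): ``taxa`` — phylum/family
    aggregation with group means +/- SEM and p; ``main_otus`` — per-phylum
    main-OTU rows with closest-taxon identity and per-phylum Total rows
    summing the printed-precision column values; ``correlations`` — main OTU
    x covariate Pearson r/p; ``alpha`` — per-group alpha diversity comparison
    (only when ``counts`` is given).
    """
    cfg = cfg or PipelineConfig()
    missing = [s for s in rel_abund.columns if s not in metadata.index]
    if missing:
        raise KeyError(f"metadata missing samples: {missing}")
    labels = metadata.loc[list(rel_abund.columns), group_col]
    group_names = sorted(labels.unique())
    if len(group_names) != 2:
        raise ValueError("report requires exactly two treatment groups")
    groups = {g: [s for s in rel_abund.columns if labels[s] == g] for g in group_names}

    def lineage_of(otu: str) -> tuple[str, ...]:
        return tuple(assignments[otu].lineage)

    # --- phylum/family aggregation -------------------------------------
    taxa_rows = []
    phyla = sorted({lineage_of(o)[1] for o in rel_abund.index})
    for phylum in phyla:
        members = [o for o in rel_abund.index if lineage_of(o)[1] == phylum]
        phylum_vec = rel_abund.loc[members].sum(axis=0)
        row = _group_row(phylum, phylum_vec, groups)
        row["level"] = "phylum"
        row["phylum"] = phylum
        taxa_rows.append(row)
        families = sorted({lineage_of(o)[4] for o in members})
        for family in families:
            fam_members = [o for o in members if lineage_of(o)[4] == family]
            fam_vec = rel_abund.loc[fam_members].sum(axis=0)
            row = _group_row(family, fam_vec, groups)
            row["level"] = "family"
            row["phylum"] = phylum
            taxa_rows.append(row)
    taxa = pd.DataFrame(taxa_rows).set_index("feature")

    # --- main OTU tables, split by phylum ------------------------------
    main = select_main_otus(rel_abund, groups, cfg.main_otu_threshold * 100.0)
    otu_rows = []
    (label_a, _), (label_b, _) = groups.items()
    for phylum in phyla:
        block = [o for o in main if lineage_of(o)[1] == phylum]
        if not block:
            continue
        for otu in block:
            row = _group_row(otu, rel_abund.loc[otu], groups)
            row["phylum"] = phylum
            a = assignments[otu]
            row["closest_taxon"] = f"{a.best_hit_id} ({a.best_hit_identity}%)"
            otu_rows.append(row)
        # Total row: column sums of the entries at printed (2-dec) precision
        total = {
            "feature": f"Total {phylum}", "phylum": phylum, "closest_taxon": "",
            f"mean_{label_a}": round(
                sum(round(r[f"mean_{label_a}"], 2) for r in otu_rows
                    if r["phylum"] == phylum and not str(r["feature"]).startswith("Total")), 2),
            f"mean_{label_b}": round(
                sum(round(r[f"mean_{label_b}"], 2) for r in otu_rows
                    if r["phylum"] == phylum and not str(r["feature"]).startswith("Total")), 2),
        }
        otu_rows.append(total)
    main_otus = pd.DataFrame(otu_rows).set_index("feature")

    # --- Pearson correlations: main OTUs x numeric covariates ----------
    covariates = [c for c in metadata.columns
                  if c != group_col and pd.api.types.is_numeric_dtype(metadata[c])]
    corr_rows = []
    for otu in main:
        for cov in covariates:
            x = rel_abund.loc[otu, list(rel_abund.columns)].to_numpy(dtype=float)
            y = metadata.loc[list(rel_abund.columns), cov].to_numpy(dtype=float)
            if x.std() == 0 or y.std() == 0:
                continue
            res = pearson(x, y, otu_id=otu, covariate=cov)
            corr_rows.append({
                "otu_id": otu, "covariate": cov, "r": res.r,
                "n": res.n, "p_value": res.p_value,
            })
    correlations = pd.DataFrame(corr_rows)

    report = {"taxa": taxa, "main_otus": main_otus, "correlations": correlations}

    # --- alpha diversity comparison ------------------------------------
    if counts is not None:
        alpha = alpha_table(counts)
        alpha_rows = []
        for index_name in ["chao1", "observed_otus", "shannon", "simpson", "coverage"]:
            row = _group_row(index_name, alpha[index_name], groups)
            alpha_rows.append(row)
        report["alpha"] = pd.DataFrame(alpha_rows).set_index("feature")

    if outdir is not None:
        import os
        os.makedirs(outdir, exist_ok=True)
        for name, frame in report.items():
            frame.to_csv(os.path.join(outdir, f"report_{name}.tsv"), sep="\t")
    return report
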