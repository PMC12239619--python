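"""Per-cohort evaluation metrics and replicate summaries.

Gains are reported in gSD units: the difference of a cohort's mean true
index value from the reference cohort's mean, divided by the reference
cohort's index standard deviation.  DH-variant traits are referenced to the
founder DH panel, cross-variant traits to a once-per-replicate cohort of
random founder crosses.  Diversity is tracked as the variance of true index
values within a cohort, the share of heterozygous genotype calls, and the
share of fixed (monomorphic) markers.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd
import scipy.stats

from .founders import Cohort
from .prediction import selection_index
from .traits import CROSS_TRAITS, DH_TRAITS, TRAIT_NAMES, TraitArchitecture, genetic_values

__all__ = ["ReferenceStats", "cohort_metrics", "summarize_replicates", "welch_tests", "plot_gain"]


@dataclasses.dataclass
class ReferenceStats:
    """Reference means/SDs used as the gSD denominator of all gains."""

    dh_trait_mean: np.ndarray  # (3,) founder DH cohort
    dh_trait_sd: np.ndarray
    dh_index_mean: float
    dh_index_sd: float
    cross_trait_mean: np.ndarray  # (3,) random-cross reference cohort
    cross_trait_sd: np.ndarray
    cross_index_mean: float
    cross_index_sd: float

    @staticmethod
    def from_cohorts(founders: Cohort, reference_cross: Cohort, arch: TraitArchitecture) -> "ReferenceStats":
        vf = genetic_values(founders, arch)[:, list(DH_TRAITS)]
        vr = genetic_values(reference_cross, arch)[:, list(CROSS_TRAITS)]
        fi = selection_index(vf)
        ri = selection_index(vr)
        return ReferenceStats(
            dh_trait_mean=vf.mean(axis=0),
            dh_trait_sd=vf.std(axis=0, ddof=1),
            dh_index_mean=float(fi.mean()),
            dh_index_sd=float(fi.std(ddof=1)),
            cross_trait_mean=vr.mean(axis=0),
            cross_trait_sd=vr.std(axis=0, ddof=1),
            cross_index_mean=float(ri.mean()),
            cross_index_sd=float(ri.std(ddof=1)),
        )


def cohort_metrics(
    cohort: Cohort,
    arch: TraitArchitecture,
    reference: ReferenceStats,
    model=None,
    truth: np.ndarray | None = None,
    values: np.ndarray | None = None,
) -> dict:
    """Evaluate one cohort: gains, genic diversity, het/fixed shares, accuracy.

    ``model`` (a :class:`~rcsim.prediction.PredictionModel`) and ``truth``
    (candidate true values per fitted trait) are optional; when supplied,
    per-trait and mean prediction accuracies are included.  ``values`` may
    carry precomputed true genetic values (n, 6) to avoid re-evaluation.
    """
    if cohort.n == 0:
        raise ValueError("cohort is empty")
    if reference is None:
        raise ValueError("reference statistics are required")
    vals = genetic_values(cohort, arch) if values is None else np.asarray(values)
    v_dh = vals[:, list(DH_TRAITS)]
    v_cr = vals[:, list(CROSS_TRAITS)]
    idx_dh = selection_index(v_dh)
    idx_cr = selection_index(v_cr)
    geno = cohort.genotypes()
    het_share = float(np.mean(geno == 1))
    fixed_share = float(np.mean(np.all(geno == geno[0], axis=0)))
    out = {
        "n": cohort.n,
        "gain_index_cross": (idx_cr.mean() - reference.cross_index_mean) / reference.cross_index_sd,
        "gain_index_dh": (idx_dh.mean() - reference.dh_index_mean) / reference.dh_index_sd,
        "var_index_cross": float(idx_cr.var(ddof=1)) if cohort.n > 1 else 0.0,
        "var_index_dh": float(idx_dh.var(ddof=1)) if cohort.n > 1 else 0.0,
        "het_share": het_share,
        "fixed_share": fixed_share,
    }
    for k, t in enumerate(DH_TRAITS):
        out[f"gain_{TRAIT_NAMES[t]}"] = (
            v_dh[:, k].mean() - reference.dh_trait_mean[k]
        ) / reference.dh_trait_sd[k]
    for k, t in enumerate(CROSS_TRAITS):
        out[f"gain_{TRAIT_NAMES[t]}"] = (
            v_cr[:, k].mean() - reference.cross_trait_mean[k]
        ) / reference.cross_trait_sd[k]
    if model is not None and truth is not None:
        accs, mean_acc = model.accuracy(truth)
        for k, a in enumerate(accs):
            out[f"accuracy_trait{k}"] = a
        out["accuracy_mean"] = mean_acc
    return out


def summarize_replicates(df: pd.DataFrame, by=("scenario", "cycle", "cohort")) -> pd.DataFrame:
    """Mean, SD and SE = SD/sqrt(n) per scenario x cycle x metric.

    ``df`` is the long replicate table from :func:`rcsim.orchestrator.run_scenario`
    (one row per replicate x cycle x cohort).  With a single replicate SD
    and SE are reported as missing.
    """
    by = [b for b in by if b in df.columns]
    value_cols = [
        c for c in df.columns if c not in by + ["replicate"] and np.issubdtype(df[c].dtype, np.number)
    ]
    rows = []
    for keys, grp in df.groupby(by):
        keys = keys if isinstance(keys, tuple) else (keys,)
        n = grp["replicate"].nunique() if "replicate" in grp.columns else len(grp)
        for c in value_cols:
            x = grp[c].to_numpy(dtype=float)
            x = x[~np.isnan(x)]
            if len(x) == 0:
                continue
            sd = float(np.std(x, ddof=1)) if len(x) > 1 else np.nan
            rows.append(
                dict(zip(by, keys))
                | {
                    "metric": c,
                    "mean": float(np.mean(x)),
                    "sd": sd,
                    "se": sd / np.sqrt(len(x)) if len(x) > 1 else np.nan,
                    "n_replicates": n,
                }
            )
    return pd.DataFrame(rows)


def welch_tests(
    df: pd.DataFrame,
    metric: str = "gain_index_cross",
    cycle: int | None = None,
    cohort: str = "F2",
) -> pd.DataFrame:
    """Pairwise Welch two-sample t-tests between scenarios on a final-cycle metric."""
    if cycle is None:
        cycle = int(df["cycle"].max())
    sub = df[(df["cycle"] == cycle)]
    if "cohort" in sub.columns:
        sub = sub[sub["cohort"] == cohort]
    scenarios = sorted(sub["scenario"].unique())
    rows = []
    for a, b in itertools.combinations_with_replacement(scenarios, 2):
        xa = sub.loc[sub["scenario"] == a, metric].dropna().to_numpy()
        xb = sub.loc[sub["scenario"] == b, metric].dropna().to_numpy()
        if a == b:
            t, p = 0.0, 1.0
        else:
            t, p = scipy.stats.ttest_ind(xa, xb, equal_var=False)
        rows.append(
            {"scenario_a": a, "scenario_b": b, "cycle": cycle, "metric": metric,
             "t": float(t), "p_value": float(p), "n_a": len(xa), "n_b": len(xb)}
        )
    return pd.DataFrame(rows)


def plot_gain(summary: pd.DataFrame, metric: str = "gain_index_cross", ax=None):
    """Gain-over-cycles line plot per scenario (requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    sub = summary[summary["metric"] == metric]
    if "cohort" in sub.columns:
        sub = sub[sub["cohort"] == "F2"]
    for scen, grp in sub.groupby("scenario"):
        grp = grp.sort_values("cycle")
        ax.plot(grp["cycle"], grp["mean"], label=str(scen))
        ax.fill_between(
            grp["cycle"], grp["mean"] - grp["se"], grp["mean"] + grp["se"], alpha=0.2
        )
    ax.set_xlabel("breeding cycle")
    ax.set_ylabel(metric)
    ax.legend()
    return ax
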