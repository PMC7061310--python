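"""Cohort-level statistics.

Four stages used to relate codon supply/demand to phenotype across a
sample cohort:

* differential features (e.g. SDAw or anticodon abundance) between two
  groups — two-tailed Wilcoxon rank-sum tests, log2 fold changes of
  group medians, Benjamini-Hochberg FDR across features;
* per-gene promoter methylation (mean beta over a strand-aware window
  from 1.5 kb upstream of the TSS to the gene end, or restricted to the
  gene body for base-resolution bisulfite data) and copy-number values
  (overlap-weighted mean of segmented log2(CN)-1), both averaged over
  the genes sharing an anticodon;
* per-isoacceptor multiple linear regression of square-root-normalised
  tRNA abundance on methylation and copy number, with t-statistic
  p-values FDR-corrected jointly across all fitted models, and an exact
  two-sided binomial test on the signs of the significant coefficients;
* Kaplan-Meier survival stratification of the patients in the bottom
  and top 40% of a codon's SDAw, compared by a two-group log-rank test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .reference import TRNAGene

logger = logging.getLogger(__name__)

DEFAULT_TSS_UPSTREAM = 1500


# ---------------------------------------------------------------------------
# differential statistics


def differential(
    matrix: pd.DataFrame, groups: Sequence[str], group_a: str, group_b: str
) -> pd.DataFrame:
    """Per-feature two-tailed Wilcoxon rank-sum tests between two groups.

    ``matrix`` is samples x features; ``groups`` labels each row.
    Returns one row per feature with ``log2fc`` (log2 of median_b over
    median_a, NaN unless both medians are positive), the rank-sum
    p-value (exact where possible, normal approximation with mid-rank
    tie handling otherwise), BH-adjusted ``q`` across features, and the
    group sizes after removing missing values.
    """
    groups = np.asarray(groups)
    rows = []
    for feat in matrix.columns:
        a = matrix.loc[groups == group_a, feat].dropna().to_numpy()
        b = matrix.loc[groups == group_b, feat].dropna().to_numpy()
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"feature {feat}: need >=2 samples per group")
        med_a, med_b = float(np.median(a)), float(np.median(b))
        log2fc = np.log2(med_b / med_a) if med_a > 0 and med_b > 0 else np.nan
        pooled = np.concatenate([a, b])
        if np.all(pooled == pooled[0]):
            p, flagged = 1.0, True
        else:
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
            flagged = False
        rows.append(
            {
                "feature": feat,
                "log2fc": log2fc,
                "p": p,
                "n_a": len(a),
                "n_b": len(b),
                "degenerate": flagged,
            }
        )
    out = pd.DataFrame(rows).set_index("feature")
    out["q"] = benjamini_hochberg(out["p"].to_numpy())
    return out


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values."""
    return multipletests(pvalues, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# methylation and copy number features


def _methylation_window(gene: TRNAGene, mode: str, upstream: int) -> tuple[int, int]:
    if mode == "bisulfite":
        return gene.start, gene.end
    if gene.strand == "+":
        return gene.start - upstream, gene.end
    return gene.start, gene.end + upstream


def promoter_methylation(
    genes: Iterable[TRNAGene],
    betas: pd.DataFrame,
    mode: str = "array",
    upstream: int = DEFAULT_TSS_UPSTREAM,
) -> tuple[pd.Series, pd.Series, float]:
    """Mean methylation beta per gene and per isoacceptor.

    ``betas`` needs columns ``chrom``, ``pos`` (0-based) and ``beta``.
    Array mode averages positions in the strand-aware window
    [TSS - upstream, gene end]; bisulfite mode restricts to the gene
    body (Pol-III promoters are intragenic).  Genes with no covered
    position are missing (NaN).  Returns (per-gene, per-isoacceptor,
    coverage fraction of genes with data).
    """
    if mode not in ("array", "bisulfite"):
        raise ValueError(f"unknown mode {mode!r}")
    per_gene = {}
    anticodons = {}
    for g in genes:
        lo, hi = _methylation_window(g, mode, upstream)
        sel = betas[(betas["chrom"] == g.chrom) & (betas["pos"] >= lo) & (betas["pos"] < hi)]
        per_gene[g.gene_id] = float(sel["beta"].mean()) if len(sel) else np.nan
        anticodons[g.gene_id] = g.anticodon
    gene_series = pd.Series(per_gene, name="beta")
    coverage = float(gene_series.notna().mean()) if len(gene_series) else 0.0
    iso = gene_series.groupby(pd.Series(anticodons)).mean()
    iso.name = "beta"
    return gene_series, iso, coverage


def gene_cna(
    genes: Iterable[TRNAGene], segments: pd.DataFrame
) -> tuple[pd.Series, pd.Series]:
    """Overlap-weighted copy-number value per gene and per isoacceptor.

    ``segments`` needs columns ``chrom``, ``start``, ``end``, ``value``
    (half-open intervals on the log2(CN)-1 scale).  A gene inside one
    segment takes its value; genes spanning a breakpoint take the
    overlap-length-weighted mean; genes with no overlap are missing.
    """
    per_gene = {}
    anticodons = {}
    for g in genes:
        sel = segments[
            (segments["chrom"] == g.chrom)
            & (segments["end"] > g.start)
            & (segments["start"] < g.end)
        ]
        if len(sel) == 0:
            per_gene[g.gene_id] = np.nan
        else:
            overlaps = np.minimum(sel["end"], g.end) - np.maximum(sel["start"], g.start)
            per_gene[g.gene_id] = float(
                np.average(sel["value"], weights=overlaps.to_numpy())
            )
        anticodons[g.gene_id] = g.anticodon
    gene_series = pd.Series(per_gene, name="cna")
    iso = gene_series.groupby(pd.Series(anticodons)).mean()
    iso.name = "cna"
    return gene_series, iso


# ---------------------------------------------------------------------------
# multiple linear regression


def fit_isoacceptor_mlr(data: pd.DataFrame) -> pd.DataFrame:
    """OLS fits of abundance ~ methylation + copy number, per model group.

    ``data`` needs columns ``isoacceptor``, ``condition``, ``abundance``
    (square-root-normalised tRNA abundance), ``me`` and ``cna``.  One
    model is fitted per (isoacceptor, condition) on complete samples.
    Coefficient t-statistic p-values are FDR-corrected jointly across
    all fitted models (columns ``q_me``, ``q_cna``).  Groups with fewer
    than 4 complete samples or a rank-deficient design are skipped and
    returned with ``skipped`` set.
    """
    import statsmodels.api as sm

    rows = []
    for (iso, cond), grp in data.groupby(["isoacceptor", "condition"], sort=True):
        sub = grp[["abundance", "me", "cna"]].dropna()
        record = {"isoacceptor": iso, "condition": cond, "n": len(sub)}
        X = sm.add_constant(sub[["me", "cna"]], has_constant="add")
        if len(sub) < 4 or np.linalg.matrix_rank(X.to_numpy()) < 3:
            rows.append(record | {"skipped": True})
            continue
        fit = sm.OLS(sub["abundance"], X).fit()
        rows.append(
            record
            | {
                "skipped": False,
                "beta0": fit.params["const"],
                "beta_me": fit.params["me"],
                "beta_cna": fit.params["cna"],
                "p_me": fit.pvalues["me"],
                "p_cna": fit.pvalues["cna"],
                "r2": fit.rsquared,
            }
        )
    out = pd.DataFrame(rows)
    fitted = out[~out["skipped"]]
    if len(fitted):
        qs = benjamini_hochberg(
            np.concatenate([fitted["p_me"].to_numpy(), fitted["p_cna"].to_numpy()])
        )
        out.loc[~out["skipped"], "q_me"] = qs[: len(fitted)]
        out.loc[~out["skipped"], "q_cna"] = qs[len(fitted) :]
    return out


def coefficient_sign_test(
    results: pd.DataFrame, which: str, alpha: float = 0.05
) -> tuple[float, int, int]:
    """Exact two-sided binomial test on significant coefficient signs.

    ``which`` is ``"me"`` or ``"cna"``.  Only coefficients with
    FDR-adjusted p below ``alpha`` enter; returns (p, n_pos, n_neg).
    With zero significant coefficients the p-value is NaN (flagged by
    the caller).
    """
    if which not in ("me", "cna"):
        raise ValueError("which must be 'me' or 'cna'")
    sig = results[(~results["skipped"]) & (results[f"q_{which}"] < alpha)]
    betas = sig[f"beta_{which}"]
    n_pos = int((betas > 0).sum())
    n_neg = int((betas < 0).sum())
    if n_pos + n_neg == 0:
        logger.warning("sign test: no significant %s coefficients", which)
        return float("nan"), 0, 0
    p = float(stats.binomtest(n_pos, n_pos + n_neg, 0.5, alternative="two-sided").pvalue)
    return p, n_pos, n_neg


# ---------------------------------------------------------------------------
# survival


@dataclass
class SurvivalResult:
    """Two-group Kaplan-Meier comparison."""

    logrank_p: float
    km_low: pd.DataFrame
    km_high: pd.DataFrame
    n_low: int
    n_high: int
    threshold_low: float = np.nan
    threshold_high: float = np.nan


def survival_by_sdaw(
    values: pd.Series, clinical: pd.DataFrame, fraction: float = 0.4
) -> SurvivalResult:
    """Stratify patients into bottom/top ``fraction`` of a score and
    compare their Kaplan-Meier curves with a log-rank test.

    ``values`` indexes patients; ``clinical`` needs columns ``time`` and
    ``event`` (1 = death, 0 = censored) on the same index.  Ties at the
    quantile boundary are broken by stable sample order (logged).
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    if not 0 < fraction < 0.5 + 1e-9:
        raise ValueError("fraction must lie in (0, 0.5]")
    shared = values.index.intersection(clinical.index)
    v = values.loc[shared].dropna()
    k = int(np.floor(fraction * len(v)))
    if k == 0:
        raise ValueError("a group with zero patients")
    order = np.argsort(v.to_numpy(), kind="stable")
    low_ids = v.index[order[:k]]
    high_ids = v.index[order[-k:]]
    if v.loc[low_ids].max() == v.loc[high_ids].min():
        logger.info("quantile boundary ties broken by stable sample order")

    def _km(ids) -> pd.DataFrame:
        kmf = KaplanMeierFitter()
        kmf.fit(clinical.loc[ids, "time"], clinical.loc[ids, "event"])
        df = kmf.survival_function_.reset_index()
        df.columns = ["time", "survival"]
        return df

    lr = logrank_test(
        clinical.loc[low_ids, "time"],
        clinical.loc[high_ids, "time"],
        event_observed_A=clinical.loc[low_ids, "event"],
        event_observed_B=clinical.loc[high_ids, "event"],
    )
    return SurvivalResult(
        logrank_p=float(lr.p_value),
        km_low=_km(low_ids),
        km_high=_km(high_ids),
        n_low=len(low_ids),
        n_high=len(high_ids),
        threshold_low=float(v.loc[low_ids].max()),
        threshold_high=float(v.loc[high_ids].min()),
    )


def select_survival_candidates(
    diff_by_condition: pd.DataFrame, alpha: float = 0.05, min_net: int = 5
) -> list[str]:
    """Codons whose differential direction is consistent across conditions.

    ``diff_by_condition`` needs columns ``feature``, ``condition``,
    ``log2fc`` and ``q``.  A codon is a candidate when the number of
    conditions where it is significantly up minus the number where it is
    significantly down exceeds ``min_net`` in absolute value.
    """
    candidates = []
    for feat, grp in diff_by_condition.groupby("feature", sort=True):
        sig = grp[grp["q"] < alpha]
        up = int((sig["log2fc"] > 0).sum())
        down = int((sig["log2fc"] < 0).sum())
        if abs(up - down) > min_net:
            candidates.append(feat)
    return candidates


def survival_scan(
    sdaw_matrix: pd.DataFrame,
    clinical: pd.DataFrame,
    candidates: Sequence[str],
    fraction: float = 0.4,
) -> pd.DataFrame:
    """Log-rank scan over candidate codons, FDR-corrected across codons.

    ``sdaw_matrix`` is patients x codons.  Returns one row per candidate
    with the log-rank ``p`` and BH-adjusted ``q``.
    """
    rows = []
    for codon in candidates:
        res = survival_by_sdaw(sdaw_matrix[codon], clinical, fraction)
        rows.append(
            {"codon": codon, "p": res.logrank_p, "n_low": res.n_low, "n_high": res.n_high}
        )
    out = pd.DataFrame(rows).set_index("codon")
    if len(out):
        out["q"] = benjamini_hochberg(out["p"].to_numpy())
    return out
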