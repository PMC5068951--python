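"""Growth-inhibition scores, robust Z-scores, tail-area FDR, and hit calls.

The growth-inhibition (GI) score of a mutant is the normalized log2 ratio
of its control to treatment barcode counts divided by the number of pool
doublings d:

    GI_i = log2(c_i / t_i) / d

with c, t library-size-normalized (counts-per-million after a pseudocount).
An unaffected mutant scores ~0; one that stops dividing under treatment
while the pool completes d doublings scores ~1.  Because control and
treatment endpoints are compared for the same strain, constitutive slow
growth cancels out of the ratio.

Sensitivity is judged on the robust Z-score — the deviation of GI from the
screen median in units of the normalized interquartile range
(NIQR = IQR / 1.349, a robust sigma) — and on a tail-area false discovery
rate computed from an empirical half-normal null fitted to the central bulk
of |Z| (an fdrtool-style re-implementation; see docs/methods.md).  A mutant
is called sensitive when it passes the FDR cutoff, in the depletion
direction, in every screen of a compound.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "NormalizedCounts",
    "RobustStats",
    "NullModel",
    "HitCalls",
    "normalize_counts",
    "gi_score",
    "robust_z",
    "tail_area_fdr",
    "score_screen",
    "call_hits",
    "classify_expressivity",
    "NIQR_FACTOR",
    "DEFAULT_FDR_CUTOFF",
    "DEFAULT_EXPRESSIVITY_CUTOFFS",
]

#: IQR of a standard normal: NIQR = IQR / 1.349 estimates sigma robustly.
NIQR_FACTOR = 1.349

DEFAULT_FDR_CUTOFF = 0.1
#: Mean-GI cutoffs (low < c_low <= medium < c_high <= high).  The published
#: screens call their own cutoffs arbitrary; these are configuration.
DEFAULT_EXPRESSIVITY_CUTOFFS = (0.25, 0.6)

CPM_SCALE = 1e6


class DegenerateScreenError(ValueError):
    """Raised when a screen's score distribution cannot support the model."""


@dataclass
class NormalizedCounts:
    """Counts-per-million after pseudocount; every column sums to 1e6."""

    frame: pd.DataFrame
    pseudocount: float


@dataclass(frozen=True)
class RobustStats:
    median: float
    iqr: float

    @property
    def niqr(self) -> float:
        return self.iqr / NIQR_FACTOR


@dataclass(frozen=True)
class NullModel:
    """Empirical half-normal null fitted to the central bulk of |Z|."""

    pi0: float  # estimated null proportion, in (0, 1]
    sigma0: float  # scale of the half-normal null
    cutoff: float  # |Z| truncation point the null was fitted below
    n: int


def normalize_counts(counts: pd.DataFrame, pseudocount: float = 1.0) -> NormalizedCounts:
    """Library-size normalization: 1e6 * (count + pc) / column_sum(count + pc)."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    zero_cols = counts.columns[(counts.sum(axis=0) == 0)]
    if len(zero_cols):
        raise ValueError(f"all-zero count column(s): {list(zero_cols)}")
    shifted = counts.astype(float) + pseudocount
    norm = shifted / shifted.sum(axis=0) * CPM_SCALE
    return NormalizedCounts(norm, pseudocount)


def gi_score(
    norm_control: pd.Series,
    norm_treatment: pd.Series,
    doublings: float = 5.0,
) -> pd.Series:
    """GI_i = log2(control_i / treatment_i) / d; missing mutants give NaN."""
    if doublings <= 0:
        raise ValueError("doublings must be > 0")
    idx = norm_control.index.union(norm_treatment.index, sort=False)
    c = norm_control.reindex(idx)
    t = norm_treatment.reindex(idx)
    gi = np.log2(c / t) / doublings
    gi.name = "gi"
    return gi


def robust_z(gi: pd.Series) -> tuple[pd.Series, RobustStats]:
    """Deviation of GI from the screen median in NIQR units.

    NIQR = IQR / 1.349 is a robust, outlier-insensitive sigma estimate, so
    strong true effects do not inflate the scale they are judged against.
    Missing GI propagates to missing Z.  A degenerate screen (NIQR = 0,
    i.e. >= 75% of scores identical) is an error.
    """
    values = gi.dropna().to_numpy(dtype=float)
    if values.size < 10:
        raise ValueError(f"need >= 10 non-missing GI values, got {values.size}")
    q1, med, q3 = np.percentile(values, [25.0, 50.0, 75.0])
    statsr = RobustStats(median=float(med), iqr=float(q3 - q1))
    if statsr.niqr <= 0:
        raise DegenerateScreenError("NIQR is zero: degenerate GI distribution")
    z = (gi - statsr.median) / statsr.niqr
    z.name = "z"
    return z, statsr


def _fit_half_normal_truncated(abs_z: np.ndarray, cutoff: float) -> float:
    """Truncated ML scale of a half-normal observed only below ``cutoff``."""
    trunc = abs_z[abs_z <= cutoff]
    if trunc.size < 10:
        raise DegenerateScreenError("too few |Z| values below the truncation cutoff")

    def nll(log_sigma: float) -> float:
        sigma = np.exp(log_sigma)
        log_pdf = np.log(2.0) + stats.norm.logpdf(trunc, scale=sigma)
        log_mass = np.log(2.0 * stats.norm.cdf(cutoff / sigma) - 1.0)
        return -(log_pdf.sum() - trunc.size * log_mass)

    scale_guess = max(np.sqrt(np.mean(trunc**2)), 1e-6)
    res = optimize.minimize_scalar(
        nll,
        bounds=(np.log(scale_guess) - 5.0, np.log(scale_guess) + 5.0),
        method="bounded",
    )
    if not res.success:
        raise DegenerateScreenError(f"half-normal null fit failed: {res.message}")
    return float(np.exp(res.x))


def tail_area_fdr(
    z: pd.Series | np.ndarray,
    central_quantile: float = 0.75,
) -> tuple[pd.Series, NullModel]:
    """Tail-area FDR of each |Z| under an empirical half-normal null.

    The null scale sigma0 is fitted by truncated maximum likelihood to the
    |Z| values below the ``central_quantile`` quantile (the central bulk,
    where true effects are assumed rare); pi0 is the null fraction implied
    by the observed central mass.  Then

        Fdr(z) = min(1, pi0 * P0(|Z*| >= |z|) / Fhat(|Z*| >= |z|))

    with Fhat the empirical exceedance, and the output forced non-increasing
    in |z|.  Missing Z propagates to missing FDR.  Raises when the central
    bulk cannot plausibly be null (implied pi0 < 0.5: more than half the
    distribution in the tail).
    """
    z_series = pd.Series(z) if not isinstance(z, pd.Series) else z
    finite_mask = np.isfinite(z_series.to_numpy(dtype=float))
    a = np.abs(z_series.to_numpy(dtype=float)[finite_mask])
    n = a.size
    if n < 100:
        raise ValueError(f"need >= 100 finite Z values, got {n}")
    cutoff = float(np.quantile(a, central_quantile))
    if cutoff <= 0:
        raise DegenerateScreenError("central |Z| quantile is zero")
    sigma0 = _fit_half_normal_truncated(a, cutoff)
    central_mass_null = 2.0 * stats.norm.cdf(cutoff / sigma0) - 1.0
    pi0 = min(1.0, float(np.mean(a <= cutoff)) / central_mass_null)
    if pi0 < 0.5:
        raise DegenerateScreenError(
            f"implied null proportion pi0 = {pi0:.3f} < 0.5: more than half of "
            "the probability mass lies in the tail; the empirical null is not credible"
        )
    # goodness of fit of the central bulk: a gross misfit (e.g. a bimodal
    # bulk where most mass is actually signal) invalidates the null model
    trunc = a[a <= cutoff]
    ks = stats.kstest(
        trunc,
        lambda x: (2.0 * stats.norm.cdf(x / sigma0) - 1.0) / central_mass_null,
    ).statistic
    if ks > 0.2:
        raise DegenerateScreenError(
            f"half-normal null misfits the central |Z| bulk (KS distance {ks:.2f}); "
            "the score distribution does not look null-dominated"
        )
    sorted_a = np.sort(a)
    exceed = (n - np.searchsorted(sorted_a, a, side="left")) / n
    p0_tail = 2.0 * stats.norm.sf(a / sigma0)
    fdr = np.minimum(1.0, pi0 * p0_tail / exceed)
    # enforce monotone non-increase in |z|: walking down from the largest
    # |z|, FDR may only grow
    order = np.argsort(a)
    fdr_sorted = fdr[order]
    out = np.empty_like(fdr)
    out[order] = np.maximum.accumulate(fdr_sorted[::-1])[::-1]
    full = np.full(z_series.shape, np.nan)
    full[finite_mask] = out
    result = pd.Series(full, index=z_series.index, name="fdr")
    return result, NullModel(pi0=pi0, sigma0=sigma0, cutoff=cutoff, n=n)


def score_screen(
    counts: pd.DataFrame,
    control: str,
    treatment: str,
    doublings: float = 5.0,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """GI, robust Z and tail-area FDR for one control/treatment screen."""
    norm = normalize_counts(counts[[control, treatment]], pseudocount)
    gi = gi_score(norm.frame[control], norm.frame[treatment], doublings)
    z, _ = robust_z(gi)
    fdr, _ = tail_area_fdr(z)
    return pd.DataFrame({"gi": gi, "z": z, "fdr": fdr})


@dataclass
class HitCalls:
    """Per-compound hit calls plus the rescreen-candidate follow-up set.

    hits
        Mutants passing the FDR cutoff, in the depletion direction, in
        every screen where they were assayed; with mean GI and expressivity.
    rescreen_candidates
        Mutants significant in >= 1 but not all of their screens — the set
        a bench follow-up (e.g. spot dilution assay) would retest.
    """

    hits: pd.DataFrame
    rescreen_candidates: pd.DataFrame
    fdr_cutoff: float


def classify_expressivity(
    mean_gi: float,
    cutoffs: tuple[float, float] = DEFAULT_EXPRESSIVITY_CUTOFFS,
) -> str:
    """Grade effect strength from mean GI: high / medium / low."""
    c_low, c_high = cutoffs
    if not 0 < c_low < c_high:
        raise ValueError("cutoffs must satisfy 0 < c_low < c_high")
    if mean_gi >= c_high:
        return "high"
    if mean_gi >= c_low:
        return "medium"
    return "low"


def call_hits(
    screens: Mapping[str, pd.DataFrame],
    fdr_cutoff: float = DEFAULT_FDR_CUTOFF,
    expressivity_cutoffs: tuple[float, float] = DEFAULT_EXPRESSIVITY_CUTOFFS,
) -> HitCalls:
    """Replicate-consistent hit calling across the screens of one compound.

    A mutant is a hit iff, in every screen where it has a score (mutants
    missing from a screen are judged only on the screens where present),
    FDR <= cutoff and GI > 0 (depletion; enrichment never qualifies).
    Mutants significant in some but not all of their screens become
    rescreen candidates.  Mutants with no score anywhere are left out of
    both lists — absence of data is never imputed either way.
    """
    if not screens:
        raise ValueError("at least one screen is required")
    if not 0 < fdr_cutoff < 1:
        raise ValueError("fdr_cutoff must lie in (0, 1)")
    screen_ids = list(screens)
    gi_mat = pd.DataFrame({sid: s["gi"] for sid, s in screens.items()})
    sig_mat = pd.DataFrame(
        {
            sid: (s["fdr"] <= fdr_cutoff) & (s["gi"] > 0)
            for sid, s in screens.items()
        }
    )
    assayed = gi_mat.notna()
    n_assayed = assayed.sum(axis=1)
    n_sig = (sig_mat & assayed).sum(axis=1)

    hit_mask = (n_assayed > 0) & (n_sig == n_assayed)
    rescreen_mask = (n_sig >= 1) & ~hit_mask

    def build(mask: pd.Series) -> pd.DataFrame:
        sub = gi_mat[mask]
        mean_gi = sub.mean(axis=1)
        frame = pd.DataFrame(
            {
                "mean_gi": mean_gi,
                "n_screens_assayed": n_assayed[mask],
                "n_screens_significant": n_sig[mask],
                "supporting_screens": [
                    ",".join(sid for sid in screen_ids if sig_mat.at[m, sid] and assayed.at[m, sid])
                    for m in sub.index
                ],
                "expressivity": [
                    classify_expressivity(g, expressivity_cutoffs) if np.isfinite(g) else "none"
                    for g in mean_gi
                ],
            }
        )
        return frame.sort_values("mean_gi", ascending=False)

    return HitCalls(
        hits=build(hit_mask),
        rescreen_candidates=build(rescreen_mask),
        fdr_cutoff=fdr_cutoff,
    )
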