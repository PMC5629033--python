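"""TMT differential abundance via a calibrated concordant-replicate fold rule.

The classifier is deliberately simple: after channel normalization, a
protein is called differential when its mutant/control abundance ratio
passes a fold threshold tau in the *same direction in both replicate
pairs* (up: r1 >= tau and r2 >= tau; down: r1 <= 1/tau and r2 <= 1/tau,
inclusive). The threshold itself is calibrated from the data: within-group
replicate log2 ratios are fitted with a Gaussian and tau is the fold window
containing a chosen coverage (default 90%) of that null distribution —
sigma_log2 = log2(1.3)/1.6449 gives the canonical tau = 1.3, i.e. "90% of
replicate ratios vary less than +/-30%".
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from scipy import optimize, stats

from .io_formats import TMTExperiment, ValidationError

__all__ = [
    "TmtConfig",
    "RatioDistributionFit",
    "DifferentialCall",
    "normalize_channels",
    "replicate_concordance",
    "fit_ratio_distribution",
    "derive_threshold",
    "call_differential",
]


@dataclass(frozen=True)
class TmtConfig:
    """Configuration for normalization, calibration and differential calling.

    fold_threshold : float
        Fold threshold tau (> 1) applied symmetrically on the log scale.
    coverage : float
        Null-coverage level used when deriving tau from a fitted ratio
        distribution (0.90 means tau spans the central 90%).
    normalization : str
        ``total_sum`` equalizes channel column totals to the mean original
        total; ``none`` is the identity (use when the matrix is already
        normalized upstream).
    replicate_pairing : str
        ``indexed`` pairs mutant_i with control_i; ``cross`` uses all four
        mutant/control channel combinations as ratios.
    ratio_mode : str
        ``per_replicate`` requires the threshold in every replicate ratio;
        ``averaged`` applies it to the geometric-mean ratio only.
    """

    fold_threshold: float = 1.3
    coverage: float = 0.90
    normalization: str = "total_sum"
    replicate_pairing: str = "indexed"
    ratio_mode: str = "per_replicate"

    def __post_init__(self) -> None:
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must be > 1")
        if not 0 < self.coverage < 1:
            raise ValueError("coverage must lie in (0, 1)")
        if self.normalization not in ("total_sum", "none"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.replicate_pairing not in ("indexed", "cross"):
            raise ValueError(f"unknown replicate_pairing {self.replicate_pairing!r}")
        if self.ratio_mode not in ("per_replicate", "averaged"):
            raise ValueError(f"unknown ratio_mode {self.ratio_mode!r}")


@dataclass(frozen=True)
class RatioDistributionFit:
    """Gaussian fit to the within-group replicate log2-ratio histogram.

    ``central90_halfwidth_log2`` is 1.6449 * sigma_log2 (the half-width of
    the central 90% interval under the fitted Gaussian);
    ``empirical_fraction_within`` is the observed fraction of ratios with
    |log2 r| < log2(fold_window). ``robust_fallback`` marks fits where
    nonlinear least squares failed or was degenerate and (median,
    1.4826*MAD) was reported instead.
    """

    mu_log2: float
    sigma_log2: float
    central90_halfwidth_log2: float
    empirical_fraction_within: float
    fold_window: float
    n_ratios: int
    robust_fallback: bool = False


@dataclass(frozen=True)
class DifferentialCall:
    """Per-protein replicate ratios and direction under the fold rule."""

    accession: str
    ratio_rep1: float
    ratio_rep2: float
    mean_ratio: float  # geometric mean of the replicate ratios
    direction: str  # up | down | none


def _require_two_replicates(tmt: TMTExperiment, group: str) -> tuple[str, str]:
    channels = tmt.channels_for(group)
    if len(channels) != 2:
        raise ValidationError(
            f"group {group!r} must have exactly 2 replicates, has {len(channels)}"
        )
    return tuple(channels[r] for r in sorted(channels))  # type: ignore[return-value]


def normalize_channels(tmt: TMTExperiment, config: TmtConfig | None = None) -> TMTExperiment:
    """Equalize channel totals (total-sum normalization).

    Each channel column is scaled so its total equals the mean of the
    original column totals; within-channel ratios between proteins are
    unchanged. ``normalization='none'`` returns the experiment untouched.
    """
    config = config or TmtConfig()
    if config.normalization == "none":
        return tmt
    totals = tmt.abundances.sum(axis=0)
    if (totals <= 0).any():
        zero = list(totals.index[totals <= 0])
        raise ValidationError(f"channel(s) with non-positive total: {zero}")
    scaled = tmt.abundances * (totals.mean() / totals)
    return TMTExperiment(scaled, tmt.channel_map)


def replicate_concordance(tmt: TMTExperiment, group: str) -> float:
    """Squared Pearson correlation of log10 abundances between replicates.

    Proteins with a zero abundance in either replicate channel are excluded
    (their log ratio is undefined); at least 3 usable proteins are required.
    """
    ch1, ch2 = _require_two_replicates(tmt, group)
    a = tmt.abundances[ch1].to_numpy(float)
    b = tmt.abundances[ch2].to_numpy(float)
    ok = (a > 0) & (b > 0)
    if ok.sum() < 3:
        raise ValidationError(f"fewer than 3 usable proteins in group {group!r}")
    r = np.corrcoef(np.log10(a[ok]), np.log10(b[ok]))[0, 1]
    return float(r * r)


def _gauss(x: np.ndarray, amp: float, mu: float, sigma: float) -> np.ndarray:
    return amp * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def fit_ratio_distribution(
    tmt: TMTExperiment, group: str, config: TmtConfig | None = None
) -> RatioDistributionFit:
    """Fit a Gaussian to the within-group replicate log2-ratio histogram.

    Ratios are replicate1/replicate2 abundances within ``group`` (zeros
    excluded). The histogram uses Freedman-Diaconis binning and the Gaussian
    is fitted by nonlinear least squares; if the fit fails to converge or
    the input is degenerate, a robust (median, 1.4826*MAD) estimate is
    reported with ``robust_fallback=True``.
    """
    config = config or TmtConfig()
    ch1, ch2 = _require_two_replicates(tmt, group)
    a = tmt.abundances[ch1].to_numpy(float)
    b = tmt.abundances[ch2].to_numpy(float)
    ok = (a > 0) & (b > 0)
    ratios = np.log2(a[ok] / b[ok])
    if ratios.size < 3:
        raise ValidationError(f"fewer than 3 usable ratios in group {group!r}")

    frac_within = float(np.mean(np.abs(ratios) < math.log2(config.fold_threshold)))
    z90 = stats.norm.ppf(0.95)

    def robust() -> RatioDistributionFit:
        mu = float(np.median(ratios))
        sigma = float(1.4826 * np.median(np.abs(ratios - mu)))
        return RatioDistributionFit(
            mu_log2=mu,
            sigma_log2=sigma,
            central90_halfwidth_log2=z90 * sigma,
            empirical_fraction_within=frac_within,
            fold_window=config.fold_threshold,
            n_ratios=int(ratios.size),
            robust_fallback=True,
        )

    if np.ptp(ratios) == 0 or np.std(ratios) == 0:
        return robust()
    try:
        hist, edges = np.histogram(ratios, bins="fd")
        centers = 0.5 * (edges[:-1] + edges[1:])
        if np.count_nonzero(hist) < 4:
            return robust()
        p0 = (float(hist.max()), float(np.mean(ratios)), float(np.std(ratios)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(_gauss, centers, hist, p0=p0, maxfev=10000)
        sigma = abs(float(popt[2]))
        if not np.isfinite(sigma) or sigma == 0:
            return robust()
    except (RuntimeError, ValueError):
        return robust()
    return RatioDistributionFit(
        mu_log2=float(popt[1]),
        sigma_log2=sigma,
        central90_halfwidth_log2=z90 * sigma,
        empirical_fraction_within=frac_within,
        fold_window=config.fold_threshold,
        n_ratios=int(ratios.size),
    )


def derive_threshold(fit: RatioDistributionFit | float, coverage: float = 0.90) -> float:
    """Fold threshold spanning ``coverage`` of the fitted null distribution.

    tau = 2 ** (z * sigma_log2) with z the two-sided normal quantile at the
    requested coverage (z = 1.6449 at 90%). With sigma_log2 =
    log2(1.3)/1.6449 this returns the canonical tau = 1.30. Callers may
    override the derived value with a fixed threshold downstream.
    """
    if not 0 < coverage < 1:
        raise ValueError("coverage must lie in (0, 1)")
    sigma = fit.sigma_log2 if isinstance(fit, RatioDistributionFit) else float(fit)
    if sigma < 0:
        raise ValueError("sigma_log2 must be >= 0")
    z = stats.norm.ppf(1 - (1 - coverage) / 2)
    return float(2.0 ** (z * sigma))


def call_differential(
    tmt: TMTExperiment,
    config: TmtConfig | None = None,
    threshold: float | None = None,
) -> tuple[list[DifferentialCall], dict[str, object]]:
    """Classify proteins as up/down/none under the concordant fold rule.

    After normalization (per ``config.normalization``), replicate ratios
    r_i = mutant_i / control_i are formed (pairing per
    ``config.replicate_pairing``). A protein is ``up`` when every ratio is
    >= tau, ``down`` when every ratio is <= 1/tau (both inclusive), else
    ``none``. Comparisons are performed as mutant >= tau*control /
    control >= tau*mutant so that swapping group labels maps up<->down
    exactly. Proteins with any zero abundance in the channels used are not
    evaluable and are excluded from the summary counts.

    Returns the evaluable calls plus a summary dict with keys ``n_total``,
    ``n_up``, ``n_down``, ``n_not_evaluable``, ``not_evaluable``
    (accessions) and ``threshold``.
    """
    config = config or TmtConfig()
    tau = float(threshold) if threshold is not None else config.fold_threshold
    if tau <= 1:
        raise ValueError("threshold must be > 1")
    norm = normalize_channels(tmt, config)
    c1, c2 = _require_two_replicates(norm, "control")
    m1, m2 = _require_two_replicates(norm, "mutant")
    if config.replicate_pairing == "indexed":
        pairs = [(m1, c1), (m2, c2)]
    else:
        pairs = [(m1, c1), (m1, c2), (m2, c1), (m2, c2)]

    mat = norm.abundances
    calls: list[DifferentialCall] = []
    not_evaluable: list[str] = []
    n_up = n_down = 0
    mut = [mat[m].to_numpy(float) for m, _ in pairs]
    ctl = [mat[c].to_numpy(float) for _, c in pairs]
    # primary reported ratios always the indexed pairs
    r1 = mat[m1].to_numpy(float)
    d1 = mat[c1].to_numpy(float)
    r2 = mat[m2].to_numpy(float)
    d2 = mat[c2].to_numpy(float)

    for i, acc in enumerate(mat.index):
        used = [m[i] for m in mut] + [c[i] for c in ctl] + [r1[i], d1[i], r2[i], d2[i]]
        if any(v == 0 for v in used):
            not_evaluable.append(str(acc))
            continue
        ratio1, ratio2 = r1[i] / d1[i], r2[i] / d2[i]
        if config.ratio_mode == "averaged":
            g = math.sqrt(ratio1 * ratio2)
            up = g >= tau
            down = g <= 1.0 / tau
        else:
            up = all(m[i] >= tau * c[i] for m, c in zip(mut, ctl))
            down = all(c[i] >= tau * m[i] for m, c in zip(mut, ctl))
        direction = "up" if up else ("down" if down else "none")
        n_up += direction == "up"
        n_down += direction == "down"
        calls.append(
            DifferentialCall(
                accession=str(acc),
                ratio_rep1=float(ratio1),
                ratio_rep2=float(ratio2),
                mean_ratio=float(math.sqrt(ratio1 * ratio2)),
                direction=direction,
            )
        )
    summary: dict[str, object] = {
        "n_total": len(calls),
        "n_up": int(n_up),
        "n_down": int(n_down),
        "n_not_evaluable": len(not_evaluable),
        "not_evaluable": not_evaluable,
        "threshold": tau,
    }
    return calls, summary
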