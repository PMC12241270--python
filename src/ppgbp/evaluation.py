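"""Agreement statistics and device-grading for BP estimates.

Implements the full reporting stack used to validate cuffless BP devices:

* point metrics R², RMSE, MAE, ME and SD of the error (sample SD, n-1),
* percentile-bootstrap confidence intervals (paired resampling),
* Bland–Altman bias and 1.96·SD limits of agreement with bootstrap CIs,
* AAMI verdict (|ME| <= 5 mmHg and SD <= 8 mmHg, inclusive),
* BHS cumulative-error grades — a grade requires ALL three of its
  thresholds: A = (60, 85, 95), B = (50, 75, 90), C = (40, 65, 85) percent
  of absolute errors within 5, 10 and 15 mmHg, else D,
* percent improvement between methods for higher- and lower-is-better
  metrics.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from typing import Callable, Dict, Sequence, Tuple

import numpy as np

from ppgbp.preprocess import InputError

BHS_THRESHOLDS_MMHG = (5.0, 10.0, 15.0)
BHS_GRADES = {
    "A": (60.0, 85.0, 95.0),
    "B": (50.0, 75.0, 90.0),
    "C": (40.0, 65.0, 85.0),
}
AAMI_ME_LIMIT = 5.0
AAMI_SD_LIMIT = 8.0


@dataclass
class PairedPredictions:
    """Estimated vs reference pressures for one target (SBP or DBP)."""

    estimates: np.ndarray
    references: np.ndarray
    target: str = "sbp"

    def __post_init__(self) -> None:
        self.estimates = np.asarray(self.estimates, dtype=float)
        self.references = np.asarray(self.references, dtype=float)
        if self.estimates.shape != self.references.shape or self.estimates.ndim != 1:
            raise InputError("estimates and references must be equal-length vectors")
        if len(self.estimates) < 2:
            raise InputError("need at least 2 paired predictions")
        if not (np.all(np.isfinite(self.estimates)) and np.all(np.isfinite(self.references))):
            raise InputError("non-finite predictions or references")

    @property
    def errors(self) -> np.ndarray:
        return self.estimates - self.references

    def resample(self, rng: np.random.Generator) -> "PairedPredictions":
        idx = rng.integers(0, len(self.estimates), size=len(self.estimates))
        return PairedPredictions(self.estimates[idx], self.references[idx], self.target)


# ------------------------------------------------------------ point metrics


def regression_metrics(pairs: PairedPredictions) -> Dict[str, float]:
    """R², RMSE, MAE, ME and sample SD of the errors.

    R² is 1 - SSE/SST against the reference mean; when the references are
    all equal R² is undefined and reported as NaN.
    """
    e = pairs.errors
    ref = pairs.references
    sst = float(np.sum((ref - ref.mean()) ** 2))
    r2 = 1.0 - float(np.sum(e**2)) / sst if sst > 0 else float("nan")
    return {
        "r2": r2,
        "rmse": float(np.sqrt(np.mean(e**2))),
        "mae": float(np.mean(np.abs(e))),
        "me": float(np.mean(e)),
        "sd": float(np.std(e, ddof=1)),
    }


# ---------------------------------------------------------------- bootstrap


def bootstrap_ci(
    statistic: Callable[[PairedPredictions], float],
    pairs: PairedPredictions,
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    max_retries: int = 100,
) -> Tuple[float, float]:
    """Percentile interval from paired resampling with replacement.

    A resample on which the statistic is undefined (NaN, e.g. zero variance
    in the references for R²) is redrawn, up to ``max_retries`` per
    iteration; if retries are exhausted the NaN is kept and propagates.
    """
    rng = np.random.default_rng(seed)
    stats = np.empty(n_boot)
    for i in range(n_boot):
        value = statistic(pairs.resample(rng))
        retries = 0
        while not math.isfinite(value) and retries < max_retries:
            value = statistic(pairs.resample(rng))
            retries += 1
        stats[i] = value
    lo, hi = np.percentile(stats, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def metrics_with_ci(
    pairs: PairedPredictions, n_boot: int = 1000, alpha: float = 0.05, seed: int = 0
) -> Dict[str, Dict]:
    """Each point metric with its bootstrap CI and ± half-width."""
    point = regression_metrics(pairs)
    out: Dict[str, Dict] = {}
    for j, (name, value) in enumerate(point.items()):
        lo, hi = bootstrap_ci(
            lambda p, _n=name: regression_metrics(p)[_n],
            pairs,
            n_boot=n_boot,
            alpha=alpha,
            seed=seed + j,
        )
        out[name] = {
            "value": value,
            "ci": (lo, hi),
            "half_width": (hi - lo) / 2.0,
        }
    return out


# ------------------------------------------------------------- Bland–Altman


@dataclass
class BlandAltmanResult:
    bias: float
    loa_low: float
    loa_high: float
    bias_ci: Tuple[float, float]
    loa_low_ci: Tuple[float, float]
    loa_high_ci: Tuple[float, float]


def bland_altman(
    pairs: PairedPredictions,
    loa_multiplier: float = 1.96,
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> BlandAltmanResult:
    """Bias and limits of agreement bias ± 1.96·SD(d), with bootstrap CIs."""

    def _stats(p: PairedPredictions) -> Tuple[float, float, float]:
        d = p.errors
        bias = float(np.mean(d))
        sd = float(np.std(d, ddof=1))
        return bias, bias - loa_multiplier * sd, bias + loa_multiplier * sd

    bias, lo, hi = _stats(pairs)
    cis = []
    for j in range(3):
        cis.append(
            bootstrap_ci(
                lambda p, _j=j: _stats(p)[_j], pairs, n_boot=n_boot, alpha=alpha, seed=seed + j
            )
        )
    return BlandAltmanResult(
        bias=bias,
        loa_low=lo,
        loa_high=hi,
        bias_ci=cis[0],
        loa_low_ci=cis[1],
        loa_high_ci=cis[2],
    )


# ----------------------------------------------------------- AAMI and BHS


@dataclass
class AAMIResult:
    me: float
    sd: float
    passes: bool


def aami_check(me: float, sd: float) -> AAMIResult:
    """AAMI accuracy criterion: |ME| <= 5 mmHg and SD <= 8 mmHg (inclusive)."""
    if not (math.isfinite(me) and math.isfinite(sd)):
        raise InputError("AAMI check requires finite ME and SD")
    return AAMIResult(me=me, sd=sd, passes=abs(me) <= AAMI_ME_LIMIT and sd <= AAMI_SD_LIMIT)


def cumulative_within(
    pairs: PairedPredictions, thresholds: Sequence[float] = BHS_THRESHOLDS_MMHG
) -> Tuple[float, ...]:
    """Percent of absolute errors within each threshold (inclusive)."""
    abs_err = np.abs(pairs.errors)
    return tuple(float(100.0 * np.mean(abs_err <= t)) for t in thresholds)


def bhs_grade(percentages: Sequence[float]) -> str:
    """Best BHS grade whose thresholds are ALL met; D if none."""
    p5, p10, p15 = percentages
    if not (0 <= p5 <= p10 <= p15 <= 100):
        raise InputError(f"invalid cumulative percentages {percentages}")
    for grade, (t5, t10, t15) in BHS_GRADES.items():
        if p5 >= t5 and p10 >= t10 and p15 >= t15:
            return grade
    return "D"


@dataclass
class BHSResult:
    pct_within_5: float
    pct_within_10: float
    pct_within_15: float
    grade: str


def bhs_result(pairs: PairedPredictions) -> BHSResult:
    pcts = cumulative_within(pairs)
    return BHSResult(*pcts, grade=bhs_grade(pcts))


# ---------------------------------------------------------- comparisons


def percent_improvement(baseline: float, improved: float, orientation: str) -> float:
    """Relative gain in percent; sign convention set by the orientation."""
    if baseline == 0:
        return float("nan")
    if orientation == "higher_better":
        return 100.0 * (improved - baseline) / baseline
    if orientation == "lower_better":
        return 100.0 * (baseline - improved) / baseline
    raise ValueError("orientation must be 'higher_better' or 'lower_better'")


# --------------------------------------------------------------- reporting


def evaluate_report(
    sbp_pairs: PairedPredictions,
    dbp_pairs: PairedPredictions,
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    loa_multiplier: float = 1.96,
) -> Dict:
    """Full per-target report: metrics+CIs, Bland–Altman, BHS, AAMI."""
    report: Dict = {"n_boot": n_boot, "alpha": alpha, "targets": {}}
    for pairs in (sbp_pairs, dbp_pairs):
        metrics = metrics_with_ci(pairs, n_boot=n_boot, alpha=alpha, seed=seed)
        ba = bland_altman(
            pairs, loa_multiplier=loa_multiplier, n_boot=n_boot, alpha=alpha, seed=seed + 10
        )
        bhs = bhs_result(pairs)
        aami = aami_check(metrics["me"]["value"], metrics["sd"]["value"])
        report["targets"][pairs.target] = {
            "n": int(len(pairs.estimates)),
            "metrics": metrics,
            "bland_altman": asdict(ba),
            "bhs": asdict(bhs),
            "aami": asdict(aami),
        }
    return report


def report_to_json(report: Dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=_jsonify)


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def report_table(report: Dict) -> str:
    """Human-readable table mirroring the standard reporting layout."""
    lines = [
        f"{'target':>6} {'n':>6} {'R2':>7} {'RMSE':>7} {'MAE':>7} {'ME':>7} "
        f"{'SD':>7} {'AAMI':>5} {'BHS':>4} {'<=5':>6} {'<=10':>6} {'<=15':>6}"
    ]
    for target, block in report["targets"].items():
        m = {k: v["value"] for k, v in block["metrics"].items()}
        lines.append(
            f"{target:>6} {block['n']:>6d} {m['r2']:>7.3f} {m['rmse']:>7.2f} "
            f"{m['mae']:>7.2f} {m['me']:>7.2f} {m['sd']:>7.2f} "
            f"{'pass' if block['aami']['passes'] else 'FAIL':>5} "
            f"{block['bhs']['grade']:>4} "
            f"{block['bhs']['pct_within_5']:>6.2f} "
            f"{block['bhs']['pct_within_10']:>6.2f} "
            f"{block['bhs']['pct_within_15']:>6.2f}"
        )
    return "\n".join(lines)


__all__ = [
    "PairedPredictions",
    "regression_metrics",
    "bootstrap_ci",
    "metrics_with_ci",
    "BlandAltmanResult",
    "bland_altman",
    "AAMIResult",
    "aami_check",
    "cumulative_within",
    "bhs_grade",
    "BHSResult",
    "bhs_result",
    "percent_improvement",
    "evaluate_report",
    "report_to_json",
    "report_table",
    "BHS_THRESHOLDS_MMHG",
    "BHS_GRADES",
]
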