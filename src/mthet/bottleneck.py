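"""Germline-bottleneck transmission model and moment estimator.

Offspring variant fractions are modelled as a single binomial sampling round
of size N from the mother's fraction.  The effective bottleneck size is then
estimated from the offspring-fraction variance:

    N_hat = p_bar (1 - p_bar) / (s^2 - measurement_sd^2)

with a bootstrap standard error.  When the measurement-corrected variance is
not positive the estimate is reported as unresolved (no drift observed).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError
from .trace_sim import stream_rng


@dataclass
class TransmissionSample:
    """Mother fraction plus her offspring's measured fractions."""

    mother_fraction: float
    offspring: list[float]
    measurement_sd: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mother_fraction <= 1.0:
            raise ValueError("mother fraction must lie in [0, 1]")
        if any(not 0.0 <= f <= 1.0 for f in self.offspring):
            raise ValueError("offspring fractions must lie in [0, 1]")
        if self.measurement_sd < 0:
            raise ValueError("measurement_sd must be nonnegative")


@dataclass
class BottleneckEstimate:
    n_hat: float  # math.inf when unresolved
    se: float | None
    n_offspring: int
    unresolved: bool = False
    ci95: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        return {
            "N_hat": None if self.unresolved else self.n_hat,
            "se": self.se,
            "n": self.n_offspring,
            "unresolved": self.unresolved,
            "ci95": list(self.ci95) if self.ci95 else None,
        }


def sample_offspring_fractions(p: float, N: int, n: int, seed: int = 0) -> np.ndarray:
    """n draws of Binomial(N, p)/N — one bottleneck pass per offspring."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if N < 1:
        raise ValueError("bottleneck size N must be >= 1")
    if n < 0:
        raise ValueError("n must be nonnegative")
    rng = stream_rng(seed, "bottleneck", N)
    return rng.binomial(N, p, size=n) / N


def _moment_estimate(fracs: np.ndarray, measurement_sd: float) -> float:
    p_bar = float(fracs.mean())
    if p_bar <= 0.0 or p_bar >= 1.0:
        raise DegenerateInputError(f"mean offspring fraction {p_bar} is degenerate")
    s2 = float(fracs.var(ddof=1)) - measurement_sd**2
    if s2 <= 1e-12:  # float fuzz on identical fractions counts as no drift
        return math.inf
    return p_bar * (1.0 - p_bar) / s2


def estimate_bottleneck_N(
    sample: TransmissionSample, n_boot: int = 200, seed: int = 0
) -> BottleneckEstimate:
    """Moment estimate of the bottleneck size with bootstrap standard error."""
    fracs = np.asarray(sample.offspring, dtype=float)
    if fracs.size < 3:
        raise ValueError("need >= 3 offspring fractions")
    n_hat = _moment_estimate(fracs, sample.measurement_sd)
    if math.isinf(n_hat):
        return BottleneckEstimate(n_hat=math.inf, se=None, n_offspring=fracs.size, unresolved=True)
    rng = stream_rng(seed, "bottleneck-boot")
    boots = []
    for _ in range(n_boot):
        resample = rng.choice(fracs, size=fracs.size, replace=True)
        try:
            est = _moment_estimate(resample, sample.measurement_sd)
        except DegenerateInputError:
            continue
        if math.isfinite(est):
            boots.append(est)
    se = float(np.std(boots, ddof=1)) if len(boots) > 1 else None
    ci = None
    if len(boots) >= 20:
        lo, hi = np.percentile(boots, [2.5, 97.5])
        ci = (float(lo), float(hi))
    return BottleneckEstimate(n_hat=n_hat, se=se, n_offspring=int(fracs.size), ci95=ci)


@dataclass
class TransmissionCSV:
    samples: dict[str, TransmissionSample] = field(default_factory=dict)


def read_transmission_csv(path, measurement_sd: float = 0.0) -> dict[str, TransmissionSample]:
    """Load (mother_id, mother_fraction, egg_id, egg_fraction) rows grouped by mother."""
    mothers: dict[str, tuple[float, list[float]]] = {}
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.DictReader(fh), start=2):
            try:
                mid = row["mother_id"].strip()
                mfrac = float(row["mother_fraction"])
                efrac = float(row["egg_fraction"])
            except (KeyError, TypeError, ValueError) as exc:
                raise ValueError(f"row {i}: unparsable transmission record ({exc})") from exc
            mothers.setdefault(mid, (mfrac, []))[1].append(efrac)
    return {
        mid: TransmissionSample(mother_fraction=mfrac, offspring=fracs, measurement_sd=measurement_sd)
        for mid, (mfrac, fracs) in mothers.items()
    }
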