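"""The shared desirability function: evaluation, scaling and fitting.

Every descriptor/class pair is modeled by the same four-parameter,
Gumbel-like single-peak curve

    f(x) = o + a * exp( -exp(-t) - t + 1 ),   t = (x - b) / c

with baseline offset ``o``, amplitude ``a > 0``, mode location ``b`` and
width ``c > 0`` (both in descriptor units).  The curve attains its
maximum ``o + a`` exactly at ``x = b`` and decays to ``o`` in both tails.
Dividing by the analytic maximum yields the desirability ``df`` in
[0, 1], equal to 1 at the mode.

Fitting minimizes the sum of squared absolute errors between histogram
counts and ``f`` evaluated at bin centers, by bounded nonlinear least
squares with a deterministic multi-start strategy.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from typing import Dict, Optional

import numpy as np
from scipy.optimize import least_squares

from qepest.descriptors import CONTINUOUS_DESCRIPTORS, DESCRIPTOR_NAMES
from qepest.histograms import (
    Histogram,
    histogram_continuous,
    histogram_discrete,
    optimal_bin_width,
)

__all__ = [
    "DesirabilityParams",
    "FitResult",
    "eval_f",
    "eval_df",
    "scale",
    "fit_desirability",
    "build_class_profile",
    "profile_to_dict",
    "profile_from_dict",
    "save_profiles",
    "load_profiles",
]

# |t| beyond this saturates the inner exponential; prevents overflow while
# leaving the double-exponential tail (which underflows to 0) exact.
_T_CLIP = 700.0


@dataclass(frozen=True)
class DesirabilityParams:
    """Coefficients of one descriptor/class desirability curve.

    ``max_value`` is the scaling divisor; it is None until :func:`scale`
    sets it to the analytic maximum ``o + a``.
    """

    o: float
    a: float
    b: float
    c: float
    max_value: Optional[float] = None
    descriptor: str = ""
    class_label: str = ""

    def __post_init__(self) -> None:
        if self.c == 0:
            raise ValueError("width parameter c must be nonzero")
        if self.a <= 0:
            raise ValueError(f"amplitude a must be > 0, got {self.a}")


@dataclass(frozen=True)
class FitResult:
    params: DesirabilityParams
    sse: float
    converged: bool
    n_points: int


def eval_f(x, params: DesirabilityParams):
    """Evaluate the unscaled curve f(x); stable for |(x-b)/c| up to ~700."""
    x = np.asarray(x, dtype=float)
    t = (x - params.b) / params.c
    inner = -np.exp(np.minimum(-t, _T_CLIP)) - t + 1.0
    out = params.o + params.a * np.exp(np.minimum(inner, _T_CLIP))
    return out if out.ndim else float(out)


def scale(params: DesirabilityParams) -> DesirabilityParams:
    """Set the scaling divisor to the analytic maximum f(b) = o + a."""
    peak = params.o + params.a
    if peak <= 0:
        raise ValueError(f"non-positive maximum o + a = {peak}")
    return replace(params, max_value=peak)


def eval_df(x, params: DesirabilityParams):
    """Scaled desirability df(x) = max(f, 0) / max_value, clamped to [0, 1]."""
    if params.max_value is None:
        raise ValueError("params not scaled: call scale() first")
    out = np.clip(eval_f(x, params) / params.max_value, 0.0, 1.0)
    return out if np.ndim(out) else float(out)


def _residuals(theta, centers, counts):
    o, a, b, c = theta
    t = (centers - b) / c
    inner = -np.exp(np.minimum(-t, _T_CLIP)) - t + 1.0
    return o + a * np.exp(np.minimum(inner, _T_CLIP)) - counts


def fit_desirability(hist: Histogram, n_starts: int = 8, seed: int = 0) -> FitResult:
    """Fit (o, a, b, c) to histogram counts at bin centers.

    Start 1 uses a data-driven heuristic (o = min count, a = count range,
    b = modal bin center, c = count-weighted standard deviation); the
    remaining starts perturb b and c by up to +/-50% with a seeded RNG.
    Bounds: o >= 0, a > 0, c > 0.  The best (lowest-SSE) converged start
    wins; if no start converges the best attempt is returned with
    ``converged=False``.

    Raises
    ------
    ValueError
        For histograms with fewer than 5 bins (four free parameters) or
        zero total count.
    """
    centers = hist.centers
    counts = hist.counts.astype(float)
    if centers.size < 5:
        raise ValueError(f"need >= 5 bins to fit 4 parameters, got {centers.size}")
    if counts.sum() <= 0:
        raise ValueError("histogram has zero total count")

    c_max = counts.max()
    o0 = counts.min()
    a0 = max(c_max - o0, 1e-6)
    b0 = centers[int(np.argmax(counts))]
    w = counts / counts.sum()
    mean = float(np.sum(w * centers))
    sd = float(np.sqrt(np.sum(w * (centers - mean) ** 2)))
    c0 = max(sd, hist.width / 2.0)

    rng = np.random.default_rng(seed)
    lo = np.array([0.0, 1e-12, -np.inf, 1e-12])
    hi = np.array([np.inf, np.inf, np.inf, np.inf])

    best = None
    for start in range(max(1, n_starts)):
        if start == 0:
            theta0 = np.array([o0, a0, b0, c0])
        else:
            fb, fc = rng.uniform(0.5, 1.5, size=2)
            theta0 = np.array([o0, a0, b0 * fb if b0 != 0 else fb - 1.0, c0 * fc])
        theta0 = np.clip(theta0, lo, hi)
        try:
            res = least_squares(_residuals, theta0, args=(centers, counts),
                                bounds=(lo, hi), method="trf", xtol=1e-12, ftol=1e-12)
        except Exception:
            continue
        sse = float(np.sum(res.fun**2))
        cand = FitResult(
            params=DesirabilityParams(
                o=float(res.x[0]), a=float(max(res.x[1], 1e-12)),
                b=float(res.x[2]), c=float(max(res.x[3], 1e-12)),
                descriptor=hist.descriptor,
            ),
            sse=sse,
            converged=bool(res.success),
            n_points=int(centers.size),
        )
        if best is None or (cand.converged and not best.converged) or (
            cand.converged == best.converged and cand.sse < best.sse
        ):
            best = cand
    if best is None:
        raise RuntimeError("all fit starts failed to evaluate")
    return best


def build_class_profile(vectors, class_label: str, seed: int = 0, n_starts: int = 8):
    """Fit the six scaled desirability curves defining one class scorer.

    MW and LogP are binned at the Shimazaki-Shinomoto optimal width; the
    four count descriptors use unit bins.  Requires at least 50 molecules.

    Returns a :class:`qepest.scoring.ClassProfile`.
    """
    from qepest.scoring import ClassProfile  # local import avoids a cycle

    vectors = list(vectors)
    if len(vectors) < 50:
        raise ValueError(f"class {class_label!r}: need >= 50 molecules, got {len(vectors)}")
    params: Dict[str, DesirabilityParams] = {}
    for name in DESCRIPTOR_NAMES:
        values = np.array([dv.get(name) for dv in vectors], dtype=float)
        try:
            if name in CONTINUOUS_DESCRIPTORS:
                width = optimal_bin_width(values).width
                hist = histogram_continuous(values, width, descriptor=name)
            else:
                hist = histogram_discrete(values, descriptor=name)
                if hist.bin_edges[0] < 0.5 and np.argmax(hist.counts) == 0:
                    # the mode sits at count 0: negative counts are
                    # structurally impossible, so a zero bin at -1 anchors
                    # the peak and blocks the amplitude/location ridge a
                    # half-peak would otherwise allow
                    hist = Histogram(
                        bin_edges=np.concatenate([[hist.bin_edges[0] - 1.0], hist.bin_edges]),
                        counts=np.concatenate([[0], hist.counts]),
                        descriptor=name,
                    )
            if hist.counts.size < 5:
                # a narrow count distribution can give < 5 unit bins; pad the
                # range so the fit stays determined (padded bins hold 0)
                hist = _pad_histogram(hist, 5)
            fit = fit_desirability(hist, n_starts=n_starts, seed=seed)
        except ValueError as exc:
            raise ValueError(f"fit failed for descriptor {name} of class {class_label}: {exc}") from exc
        params[name] = scale(replace(fit.params, class_label=class_label))
    return ClassProfile(class_label=class_label, params=params)


def _pad_histogram(hist: Histogram, min_bins: int) -> Histogram:
    counts = hist.counts
    edges = hist.bin_edges
    w = hist.width
    while counts.size < min_bins:
        counts = np.concatenate([[0], counts, [0]])
        edges = np.concatenate([[edges[0] - w], edges, [edges[-1] + w]])
    return Histogram(bin_edges=edges, counts=counts, descriptor=hist.descriptor)


# -- coefficient config (JSON) -------------------------------------------------
# Schema: {class: {descriptor: {o, a, b, c, max_value}}}

def profile_to_dict(profile) -> dict:
    return {
        name: {"o": p.o, "a": p.a, "b": p.b, "c": p.c, "max_value": p.max_value}
        for name, p in profile.params.items()
    }


def profile_from_dict(class_label: str, d: dict):
    from qepest.scoring import ClassProfile

    params = {}
    for name in DESCRIPTOR_NAMES:
        if name not in d:
            raise ValueError(f"profile for class {class_label!r} missing descriptor {name!r}")
        entry = d[name]
        params[name] = DesirabilityParams(
            o=float(entry["o"]), a=float(entry["a"]), b=float(entry["b"]),
            c=float(entry["c"]), max_value=float(entry["max_value"]),
            descriptor=name, class_label=class_label,
        )
    return ClassProfile(class_label=class_label, params=params)


def save_profiles(path, profiles: dict) -> None:
    """Write {class: {descriptor: coefficients}} JSON for the H/I/F profiles."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({label: profile_to_dict(p) for label, p in profiles.items()},
                  fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_profiles(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    return {label: profile_from_dict(label, d) for label, d in raw.items()}
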