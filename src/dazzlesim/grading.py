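"""Grey analytic hierarchy process (G-AHP) grading of laser visual interference.

Scenario measurements are scored through a four-criterion hierarchy --

* U-A incident laser radiation characteristics (indicators A1-A5),
* U-B extent of retinal physiological damage (B1-B2),
* U-C retinal imaging characteristics (C1-C3),
* U-D degree of laser glare perception (D1-D5),

each indicator carrying 1-3 leaf factors -- then aggregated bottom-up
with AHP weights derived from pairwise judgment matrices, classified
into grey classes (Low / Moderate / High / Extremely High) by
trapezoidal whitening functions over per-criterion intervals, and mapped
to an interference Level I-IV.

The expert judgment matrices behind the original grading are not
published; the shipped defaults are neutral (all-ones matrices, equal
weights) and replaceable through config.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Hierarchy shape: criterion -> indicator -> leaf factor names.
DEFAULT_HIERARCHY: dict[str, dict[str, list[str]]] = {
    "U-A": {
        "A1": ["A11", "A12", "A13"],
        "A2": ["A21", "A22", "A23"],
        "A3": ["A31", "A32"],
        "A4": ["A41", "A42"],
        "A5": ["A51", "A52", "A53"],
    },
    "U-B": {
        "B1": ["B11", "B12", "B13"],
        "B2": ["B21", "B22"],
    },
    "U-C": {
        "C1": ["C11", "C12", "C13"],
        "C2": ["C21", "C22"],
        "C3": ["C31", "C32"],
    },
    "U-D": {
        "D1": ["D11", "D12"],
        "D2": ["D21", "D22"],
        "D3": ["D31", "D32"],
        "D4": ["D41", "D42"],
        "D5": ["D51"],
    },
}

CRITERIA = list(DEFAULT_HIERARCHY)

#: Grey-class intervals per criterion: Low / Moderate / High / Extremely High.
DEFAULT_CLASS_INTERVALS: dict[str, list[tuple[float, float]]] = {
    "U-A": [(0, 2), (2, 4), (4, 5), (5, 6)],
    "U-B": [(0, 3), (3, 5), (5, 6), (6, 9)],
    "U-C": [(0, 2), (2, 3), (3, 4), (4, 5)],
    "U-D": [(0, 2), (2, 3), (3, 4), (4, 5)],
}

CLASS_NAMES = ["Low", "Moderate", "High", "Extremely High"]
LEVELS = ["I", "II", "III", "IV"]

LEVEL_DESCRIPTIONS = {
    "I": ("No discomfort; produces less visual obscuration.", "Class 1"),
    "II": (
        "Piercing; produces much visual obscuration. Self-healing without "
        "treatment.",
        "Class 1M",
    ),
    "III": (
        "Piercing and dizziness; produces much visual obscuration. "
        "Self-healing without treatment.",
        "Class 2",
    ),
    "IV": (
        "Strong piercing, dizziness, and burning sensation; produces much or "
        "complete visual obscuration. Recoverable after treatment.",
        "Class 2M",
    ),
}

#: Saaty random consistency index by matrix order.
_RANDOM_INDEX = [0.0, 0.0, 0.0, 0.58, 0.90, 1.12, 1.24, 1.32, 1.41, 1.45, 1.49]


@dataclass(frozen=True)
class GreyClassSpec:
    """Grey-class intervals and whitening-band width.

    ``boundary_band`` is the fraction of the narrower adjacent interval
    over which memberships crossfade linearly at each internal boundary.
    """

    intervals: dict[str, list[tuple[float, float]]] = field(
        default_factory=lambda: {
            k: list(v) for k, v in DEFAULT_CLASS_INTERVALS.items()
        }
    )
    boundary_band: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 < self.boundary_band <= 0.5):
            raise ValueError("boundary_band must lie in (0, 0.5]")
        for crit, ivals in self.intervals.items():
            for (lo1, hi1), (lo2, hi2) in zip(ivals, ivals[1:]):
                if hi1 != lo2 or hi1 <= lo1 or hi2 <= lo2:
                    raise ValueError(
                        f"intervals for {crit} must be contiguous and increasing"
                    )


# ---------------------------------------------------------------------------
# AHP weights
# ---------------------------------------------------------------------------

def validate_judgment_matrix(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("judgment matrix must be square")
    if np.any(m <= 0):
        raise ValueError("judgment matrix entries must be positive")
    if not np.allclose(np.diag(m), 1.0, atol=1e-9):
        raise ValueError("judgment matrix diagonal must be 1")
    if not np.allclose(m * m.T, 1.0, atol=1e-6):
        raise ValueError("judgment matrix must be reciprocal (a_ji = 1/a_ij)")
    return m


def weights_from_matrix(m: np.ndarray) -> tuple[np.ndarray, float]:
    """AHP weights by the geometric-mean (logarithmic least squares) method.

    Returns the normalized weight vector and Saaty's consistency ratio
    CR = CI/RI; a warning is logged for CR > 0.1 (inconsistent
    judgments).  CR is 0 for orders below 3.
    """
    m = validate_judgment_matrix(m)
    n = m.shape[0]
    w = np.exp(np.mean(np.log(m), axis=1))
    w = w / w.sum()
    lam_max = float(np.mean((m @ w) / w))
    if n < 3:
        cr = 0.0
    else:
        ci = (lam_max - n) / (n - 1)
        ri = _RANDOM_INDEX[n] if n < len(_RANDOM_INDEX) else 1.49
        cr = ci / ri
    if cr > 0.1:
        logger.warning("judgment matrix consistency ratio %.3f > 0.1", cr)
    return w, cr


def _equal_matrix(n: int) -> np.ndarray:
    return np.ones((n, n))


def default_matrices(
    hierarchy: dict[str, dict[str, list[str]]] | None = None,
) -> dict[str, np.ndarray]:
    """Neutral all-ones judgment matrices for every internal node.

    Keys: each criterion name (over its indicators) and each indicator
    name (over its leaves).
    """
    hierarchy = hierarchy or DEFAULT_HIERARCHY
    mats: dict[str, np.ndarray] = {}
    for crit, indicators in hierarchy.items():
        mats[crit] = _equal_matrix(len(indicators))
        for ind, leaves in indicators.items():
            mats[ind] = _equal_matrix(len(leaves))
    return mats


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def aggregate_scores(
    hierarchy: dict[str, dict[str, list[str]]],
    leaf_scores: dict[str, float],
    matrices: dict[str, np.ndarray] | None = None,
) -> dict[str, float]:
    """Bottom-up weighted aggregation of leaf scores to criterion scores.

    Indicator score = AHP-weighted sum of its factor scores; criterion
    score = AHP-weighted sum of its indicator scores.  Scores therefore
    stay within the convex hull of the leaf scores.
    """
    matrices = matrices or default_matrices(hierarchy)
    out: dict[str, float] = {}
    for crit, indicators in hierarchy.items():
        ind_scores = []
        for ind, leaves in indicators.items():
            missing = [leaf for leaf in leaves if leaf not in leaf_scores]
            if missing:
                raise KeyError(f"missing leaf score(s): {', '.join(missing)}")
            w, _ = weights_from_matrix(
                matrices.get(ind, _equal_matrix(len(leaves)))
            )
            ind_scores.append(
                float(np.dot(w, [leaf_scores[leaf] for leaf in leaves]))
            )
        w, _ = weights_from_matrix(
            matrices.get(crit, _equal_matrix(len(indicators)))
        )
        out[crit] = float(np.dot(w, ind_scores))
    return out


# ---------------------------------------------------------------------------
# Grey classification
# ---------------------------------------------------------------------------

def grey_classify(
    score: float, spec: GreyClassSpec, criterion: str
) -> np.ndarray:
    """Whitening memberships of a criterion score in the four grey classes.

    Trapezoidal memberships: full membership on interval interiors,
    linear crossfade over a band of ``spec.boundary_band`` times the
    narrower adjacent interval at each internal boundary, so memberships
    always sum to 1 and a boundary point splits 0.5/0.5.  Scores above
    the top interval are clamped with a warning.
    """
    ivals = spec.intervals[criterion]
    top = ivals[-1][1]
    if score < 0:
        raise ValueError("score must be non-negative")
    if score > top:
        logger.warning(
            "score %.3g above the top interval for %s; clamping", score, criterion
        )
        score = top
    n = len(ivals)
    memb = np.zeros(n)
    # locate containing interval
    idx = n - 1
    for i, (lo, hi) in enumerate(ivals):
        if score < hi or i == n - 1:
            idx = i
            break
    lo, hi = ivals[idx]
    memb[idx] = 1.0
    # crossfade near the lower boundary (shared with class idx-1)
    if idx > 0:
        band = spec.boundary_band * min(hi - lo, ivals[idx - 1][1] - ivals[idx - 1][0])
        if score < lo + band:
            f = 0.5 + 0.5 * (score - lo) / band
            memb[idx] = f
            memb[idx - 1] = 1.0 - f
    # crossfade near the upper boundary (shared with class idx+1)
    if idx < n - 1:
        band = spec.boundary_band * min(hi - lo, ivals[idx + 1][1] - ivals[idx + 1][0])
        if score > hi - band:
            f = 0.5 + 0.5 * (hi - score) / band
            memb[idx] = f
            memb[idx + 1] = 1.0 - f
    return memb


def assign_level(
    memberships: dict[str, np.ndarray],
    spec: GreyClassSpec | None = None,
    criterion_weights: np.ndarray | None = None,
) -> dict:
    """Combine per-criterion grey memberships into an overall Level I-IV.

    The combined class membership is the criterion-weighted mean of the
    per-criterion membership vectors; the class with maximal combined
    membership wins, ties broken toward the more severe level.  Returns
    the level, its narrative description and IEC class label, and the
    combined memberships.
    """
    crits = list(memberships)
    if criterion_weights is None:
        criterion_weights = np.full(len(crits), 1.0 / len(crits))
    criterion_weights = np.asarray(criterion_weights, dtype=float)
    if criterion_weights.shape != (len(crits),):
        raise ValueError("criterion_weights shape mismatch")
    criterion_weights = criterion_weights / criterion_weights.sum()
    combined = np.zeros(len(CLASS_NAMES))
    for w, crit in zip(criterion_weights, crits):
        combined += w * np.asarray(memberships[crit])
    # argmax with severity tie-break: scan from the most severe class down
    best = len(combined) - 1 - int(np.argmax(combined[::-1]))
    level = LEVELS[best]
    desc, iec = LEVEL_DESCRIPTIONS[level]
    return {
        "level": level,
        "class": CLASS_NAMES[best],
        "description": desc,
        "iec_class": iec,
        "combined_memberships": combined,
    }


# ---------------------------------------------------------------------------
# Measurement -> leaf-score rubric
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioMeasurement:
    """Measured quantities for one scenario.

    ``spot_diameter_um`` may be ``None`` with ``all_covered=True`` when
    the spot saturates the whole detector.
    """

    spot_diameter_um: float | None
    eye_irradiance_mw_cm2: float
    occlusion_angle_deg: float
    all_covered: bool = False
    leaf_scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.spot_diameter_um is None and not self.all_covered:
            raise ValueError("spot diameter required unless all_covered")
        for name, v in (
            ("eye_irradiance", self.eye_irradiance_mw_cm2),
            ("occlusion_angle", self.occlusion_angle_deg),
        ):
            if v < 0:
                raise ValueError(f"{name} must be non-negative")


def _piecewise(x, points):
    xs, ys = zip(*points)
    return float(np.interp(x, xs, ys))


def default_leaf_scores(
    m: ScenarioMeasurement,
    mpe_mw_cm2: float = 2.55,
    detector_diameter_um: float = 2 * 5113.0,
    hierarchy: dict | None = None,
    intervals: dict | None = None,
) -> dict[str, float]:
    """Map the three scenario measurements onto hierarchy leaf scores.

    Each criterion has a driving measurement, mapped piecewise-linearly
    (log scale for irradiance) onto that criterion's full grey range:

    * U-A <- eye irradiance relative to 1e-3..10 mW/cm^2 (log);
    * U-B <- irradiance relative to the MPE (0..2x);
    * U-C <- retinal spot diameter relative to the detector diameter;
    * U-D <- occlusion angle 0..12 degrees.

    All leaves under a criterion inherit the driving score unless an
    explicit value is supplied in ``m.leaf_scores``.
    """
    hierarchy = hierarchy or DEFAULT_HIERARCHY
    intervals = intervals or DEFAULT_CLASS_INTERVALS
    tops = {c: intervals[c][-1][1] for c in hierarchy}

    logp = np.log10(max(m.eye_irradiance_mw_cm2, 1e-6))
    driving = {
        "U-A": _piecewise(logp, [(-3, 0.0), (1, tops["U-A"])]),
        "U-B": _piecewise(
            m.eye_irradiance_mw_cm2 / mpe_mw_cm2, [(0, 0.0), (2, tops["U-B"])]
        ),
        "U-C": _piecewise(
            detector_diameter_um
            if m.all_covered
            else m.spot_diameter_um,
            [(0, 0.0), (detector_diameter_um, tops["U-C"])],
        ),
        "U-D": _piecewise(m.occlusion_angle_deg, [(0, 0.0), (12, tops["U-D"])]),
    }
    scores: dict[str, float] = {}
    for crit, indicators in hierarchy.items():
        for leaves in indicators.values():
            for leaf in leaves:
                scores[leaf] = m.leaf_scores.get(leaf, driving[crit])
    return scores


def grade_measurement(
    m: ScenarioMeasurement,
    matrices: dict[str, np.ndarray] | None = None,
    spec: GreyClassSpec | None = None,
    hierarchy: dict | None = None,
) -> dict:
    """Full grading pipeline: measurement -> E-scores -> memberships -> Level."""
    hierarchy = hierarchy or DEFAULT_HIERARCHY
    spec = spec or GreyClassSpec()
    leaf_scores = default_leaf_scores(m, hierarchy=hierarchy, intervals=spec.intervals)
    e_scores = aggregate_scores(hierarchy, leaf_scores, matrices)
    memberships = {
        crit: grey_classify(score, spec, crit) for crit, score in e_scores.items()
    }
    result = assign_level(memberships, spec)
    result["e_scores"] = e_scores
    result["memberships"] = memberships
    return result
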