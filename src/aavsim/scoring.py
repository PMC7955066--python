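"""Peak centroiding and simulation-vs-experiment scoring.

Scores compare peak *positions* only: peak heights in native MS of
megadalton assemblies are distorted by transient averaging, baseline
correction and the charging-offset estimate, so they are deliberately not
part of the score.  The pipeline is: detect centroids in both spectra,
match them one-to-one within half the average experimental peak spacing,
average the absolute deviations, add a 1 Th penalty per unmatched peak,
and convert the result to a score with a Gaussian (mu=0, sigma=10 Th)
normalized so a perfect match scores 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .spectrum import Spectrum

__all__ = [
    "ScoringConfig",
    "CentroidList",
    "MatchResult",
    "detect_centroids",
    "match_centroids",
    "average_deviation",
    "deviation_score",
    "score_spectra",
]


@dataclass(frozen=True)
class ScoringConfig:
    """Parameters of the centroid-matching score.

    Attributes
    ----------
    score_sigma
        Width (Th) of the Gaussian converting average deviation to a score.
    unmatched_penalty
        Th added to the average deviation per unmatched peak (on either side).
    match_tolerance_factor
        Matching tolerance as a fraction of the average spacing between
        adjacent experimental centroids (0.5 = half the average distance).
    min_peak_rel_height
        Peak-detection threshold relative to the most intense bin.
    penalty_mode
        How the 1 Th penalty for unmatched peaks enters the average
        deviation.  ``"add"`` (default): each unmatched peak adds
        ``unmatched_penalty`` Th to the final average, so simulations that
        predict spurious peaks or miss real ones are penalized regardless
        of how well the remaining peaks line up.  ``"as_deviation"``:
        unmatched peaks enter the average as pseudo-deviations of
        ``unmatched_penalty`` Th; note that under this reading a simulation
        matching *nothing* averages exactly 1 Th and can outscore a good
        match with realistic sub-Th..few-Th deviations, so it is kept only
        as the alternative interpretation.
    """

    score_sigma: float = 10.0
    unmatched_penalty: float = 1.0
    match_tolerance_factor: float = 0.5
    min_peak_rel_height: float = 0.02
    penalty_mode: str = "add"

    def __post_init__(self):
        if self.score_sigma <= 0:
            raise ValueError("score_sigma must be positive")
        if not 0 < self.match_tolerance_factor <= 1:
            raise ValueError("match_tolerance_factor must be in (0, 1]")
        if self.penalty_mode not in ("add", "as_deviation"):
            raise ValueError("penalty_mode must be 'add' or 'as_deviation'")


@dataclass
class CentroidList:
    """Detected peak centroids: strictly increasing m/z with apex intensities."""

    mz: np.ndarray
    intensity: np.ndarray
    source: str = "unknown"

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.size and np.any(np.diff(self.mz) <= 0):
            raise ValueError("centroid m/z positions must be strictly increasing")

    def __len__(self) -> int:
        return self.mz.size

    def mean_spacing(self) -> float:
        """Average distance between adjacent centroids (inf if fewer than 2)."""
        if len(self) < 2:
            return np.inf
        return float(np.mean(np.diff(self.mz)))

    def save_text(self, path) -> None:
        np.savetxt(path, np.column_stack([self.mz, self.intensity]),
                   fmt="%.6f\t%.8e", header=f"source: {self.source}")

    @classmethod
    def load_text(cls, path, source: str = "unknown") -> "CentroidList":
        data = np.loadtxt(path, ndmin=2)
        return cls(data[:, 0], data[:, 1], source)


@dataclass
class MatchResult:
    """Outcome of matching two centroid lists and scoring the deviations."""

    experimental_mz: np.ndarray
    simulated_mz: np.ndarray
    deviations: np.ndarray
    unmatched_experimental: int
    unmatched_simulated: int
    tolerance: float
    average_deviation: float = np.nan
    score: float = np.nan

    @property
    def n_matched(self) -> int:
        return self.deviations.size

    def to_json(self, path=None) -> str:
        payload = {
            "pairs": [
                {"experimental_mz": float(e), "simulated_mz": float(s), "deviation": float(d)}
                for e, s, d in zip(self.experimental_mz, self.simulated_mz, self.deviations)
            ],
            "n_matched": self.n_matched,
            "unmatched_experimental": self.unmatched_experimental,
            "unmatched_simulated": self.unmatched_simulated,
            "tolerance": float(self.tolerance),
            "average_deviation": float(self.average_deviation),
            "score": float(self.score),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def detect_centroids(spectrum: Spectrum, config: ScoringConfig = ScoringConfig()) -> CentroidList:
    """Find local maxima above threshold with parabolic apex refinement.

    Maxima must both exceed ``min_peak_rel_height`` x the strongest bin and
    have at least that much topographic prominence, which suppresses the
    shallow ripple that baseline correction leaves on composite peaks.  The
    apex of each detected peak is refined by fitting a parabola through the
    three bins around the maximum, giving sub-bin centroid positions.  An
    all-zero (or all-below-threshold) spectrum yields an empty list.
    """
    y = spectrum.intensity
    top = y.max()
    if top <= 0:
        return CentroidList(np.empty(0), np.empty(0), spectrum.metadata.get("source", "unknown"))
    threshold = config.min_peak_rel_height * top
    idx, _ = find_peaks(y, height=threshold, prominence=threshold)
    mz = spectrum.mz[idx].copy()
    apex = y[idx].copy()
    interior = (idx > 0) & (idx < y.size - 1)
    ii = idx[interior]
    ym1, y0, yp1 = y[ii - 1], y[ii], y[ii + 1]
    denom = ym1 - 2.0 * y0 + yp1
    shift = np.zeros(ii.size)
    ok = denom < 0
    shift[ok] = 0.5 * (ym1[ok] - yp1[ok]) / denom[ok]
    mz[interior] += shift * spectrum.step
    apex[interior] = y0 - 0.25 * (ym1 - yp1) * shift
    return CentroidList(mz, apex, spectrum.metadata.get("source", "unknown"))


def match_centroids(
    experimental: CentroidList,
    simulated: CentroidList,
    config: ScoringConfig = ScoringConfig(),
) -> MatchResult:
    """One-to-one greedy centroid matching within the spacing tolerance.

    Candidate pairs within ``match_tolerance_factor`` x the average adjacent
    spacing of the *experimental* centroids are accepted in order of
    increasing absolute deviation, each centroid being used at most once.
    The tolerance is derived from the experimental list alone so it stays
    constant across a screen and scores remain comparable.
    """
    spacing = experimental.mean_spacing()
    tolerance = config.match_tolerance_factor * spacing
    ne, ns = len(experimental), len(simulated)
    if ne == 0 or ns == 0:
        return MatchResult(np.empty(0), np.empty(0), np.empty(0), ne, ns, tolerance)
    diff = np.abs(experimental.mz[:, None] - simulated.mz[None, :])
    ei, si = np.nonzero(diff <= tolerance)
    order = np.argsort(diff[ei, si], kind="stable")
    used_e = np.zeros(ne, dtype=bool)
    used_s = np.zeros(ns, dtype=bool)
    pairs = []
    for k in order:
        e, s = ei[k], si[k]
        if not used_e[e] and not used_s[s]:
            used_e[e] = used_s[s] = True
            pairs.append((e, s))
    pairs.sort()
    e_idx = np.array([p[0] for p in pairs], dtype=int)
    s_idx = np.array([p[1] for p in pairs], dtype=int)
    e_mz = experimental.mz[e_idx] if pairs else np.empty(0)
    s_mz = simulated.mz[s_idx] if pairs else np.empty(0)
    return MatchResult(
        e_mz, s_mz, np.abs(e_mz - s_mz),
        int(ne - len(pairs)), int(ns - len(pairs)), tolerance,
    )


def average_deviation(match: MatchResult, config: ScoringConfig = ScoringConfig()) -> float:
    """Mean absolute deviation of matched pairs plus unmatched-peak penalties.

    Returns NaN when there are no peaks at all (scored as 0 downstream).
    """
    n_unmatched = match.unmatched_experimental + match.unmatched_simulated
    if match.n_matched == 0 and n_unmatched == 0:
        return np.nan
    if config.penalty_mode == "as_deviation":
        total = match.deviations.sum() + config.unmatched_penalty * n_unmatched
        return float(total / (match.n_matched + n_unmatched))
    if match.n_matched == 0:
        base = 0.0
    else:
        base = float(np.mean(match.deviations))
    return base + config.unmatched_penalty * n_unmatched


def deviation_score(deviation: float, config: ScoringConfig = ScoringConfig()) -> float:
    """Gaussian score ``exp(-dev^2 / (2 sigma^2))``; 1 at zero deviation.

    NaN deviations (no peaks) score 0, the worst possible outcome.
    """
    if deviation is None or np.isnan(deviation):
        return 0.0
    if deviation < 0:
        raise ValueError("deviation must be nonnegative")
    return float(np.exp(-(deviation**2) / (2.0 * config.score_sigma**2)))


def score_spectra(
    experimental: Spectrum | CentroidList,
    simulated: Spectrum | CentroidList,
    config: ScoringConfig = ScoringConfig(),
) -> MatchResult:
    """Detect (if needed), match and score; returns a complete MatchResult."""
    if isinstance(experimental, Spectrum):
        experimental = detect_centroids(experimental, config)
    if isinstance(simulated, Spectrum):
        simulated = detect_centroids(simulated, config)
    match = match_centroids(experimental, simulated, config)
    match.average_deviation = average_deviation(match, config)
    match.score = deviation_score(match.average_deviation, config)
    return match
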