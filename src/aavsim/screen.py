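"""Systematic VP-ratio screening against an experimental spectrum.

The screen walks bulk VP1/VP2 percentages on an integer grid (VP3% =
100% - VP1% - VP2%), and for every grid point rebuilds the multinomial
capsid ensemble, recalibrates the charging offset ``b`` so the simulated
envelope populates the same m/z region as the experiment, simulates the
spectrum, and scores it against the experimental centroids.  The
experimental spectrum is centroided once per screen; its centroid list and
matching tolerance are shared by all grid points so scores are comparable.

Because ensemble mean masses range from ~3.5 MDa (all VP3) to ~4.7 MDa
(all VP1), recalibrating ``b`` per point is essential: without it most of
the grid would simulate into an empty m/z window.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scoring import (
    CentroidList,
    ScoringConfig,
    detect_centroids,
    score_spectra,
)
from .simulate import (
    InstrumentModel,
    baseline_correct,
    calibrate_charge_offset,
    ensemble_ions,
    render_spectrum,
)
from .spectrum import Spectrum
from .stoichiometry import AssemblyModel, VPRatio, build_ensemble

__all__ = ["ScreenGrid", "screen_ratios", "best_ratio"]

logger = logging.getLogger(__name__)

# Ensemble entries below this fraction of the modal probability contribute
# nothing visible to the rendered spectrum and are skipped for speed.
DEFAULT_MIN_REL_ABUNDANCE = 1e-5


@dataclass
class ScreenGrid:
    """Scores of a VP1%/VP2% grid search.

    ``scores`` and ``offsets`` are (101, 101) arrays indexed by integer
    VP1% (rows) and VP2% (columns); cells that were not evaluated (or are
    infeasible, VP1% + VP2% > 100) hold NaN.
    """

    step: int
    scores: np.ndarray
    offsets: np.ndarray
    n_points: int

    def evaluated(self) -> np.ndarray:
        return ~np.isnan(self.scores)

    def to_tsv(self, path) -> None:
        """Write the score matrix (rows VP1%, columns VP2%) as TSV."""
        rows = np.nonzero(self.evaluated().any(axis=1))[0]
        cols = np.nonzero(self.evaluated().any(axis=0))[0]
        df = pd.DataFrame(self.scores[np.ix_(rows, cols)],
                          index=pd.Index(rows, name="vp1_percent"),
                          columns=pd.Index(cols, name="vp2_percent"))
        df.to_csv(path, sep="\t")

    def summary(self) -> dict:
        vp1, vp2, score, offset = best_ratio(self, as_indices=True)
        return {
            "best_vp1": int(vp1),
            "best_vp2": int(vp2),
            "best_vp3": int(100 - vp1 - vp2),
            "score": float(score),
            "offset_b": float(offset),
            "n_points": int(self.n_points),
            "step": int(self.step),
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.summary(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _grid_points(step: int) -> list[tuple[int, int]]:
    return [(v1, v2) for v1 in range(0, 101, step) for v2 in range(0, 101 - v1, step)]


# Stop refining b once the simulated and experimental alignment statistics
# agree to this many Thomson (well below the centroid-matching tolerance).
_B_ALIGN_TOL_TH = 1.0
_B_MAX_ITER = 6


def _alignment_stat(centroids: CentroidList) -> float:
    """Apex-weighted mean centroid position: robust to smooth background."""
    return float(np.average(centroids.mz, weights=centroids.intensity))


def _evaluate_point(
    v1: int,
    v2: int,
    experimental_centroids: CentroidList,
    exp_stat: float,
    model: AssemblyModel,
    instrument: InstrumentModel,
    scoring: ScoringConfig,
    min_rel_abundance: float,
    mean_gap_hint: float = 0.0,
    mean_mode: str = "intensity",
) -> tuple[float, float, float]:
    """Score one grid point; returns (score, offset_b, alignment_gap).

    The charging offset is initialized with the closed-form calibration and
    then refined by Newton iteration until the baseline-corrected
    simulation populates the same (intensity-weighted) mean m/z as the
    experiment: baseline correction removes the unresolved composite
    asymmetrically, shifting the mean by hundreds of Th relative to the
    plain ion mean the closed formula assumes.  ``mean_gap_hint`` (the
    offset between the alignment statistic and the plain ion-intensity
    mean at the previously evaluated point) warm-starts the iteration.
    """
    ratio = VPRatio(v1, v2, 100 - v1 - v2)
    ensemble = build_ensemble(ratio, model)
    if min_rel_abundance > 0:
        ensemble = ensemble.truncate(min_rel_abundance)
    mean_mass = ensemble.mean_mass
    target = exp_stat - mean_gap_hint
    b = calibrate_charge_offset(mean_mass, target if target > 0 else exp_stat,
                                instrument.charging)
    gap = mean_gap_hint
    dmz_db = exp_stat**2 / mean_mass  # |d(mz)/db| at the envelope centre
    sim = None
    sim_cen = None
    b_prev = delta_prev = None
    for _ in range(_B_MAX_ITER):
        inst_b = instrument.with_offset(b)
        ions = ensemble_ions(ensemble, inst_b)
        raw = render_spectrum(ions, inst_b)
        sim = baseline_correct(raw, inst_b).max_normalized()
        sim_cen = detect_centroids(sim, scoring)
        if len(sim_cen) == 0:
            break
        stat = _alignment_stat(sim_cen) if mean_mode == "centroid" else sim.mean_mz()
        gap = stat - float(np.average(ions.mz, weights=ions.intensity))
        delta = stat - exp_stat
        if abs(delta) <= _B_ALIGN_TOL_TH:
            break
        # Newton step from the analytic slope, upgraded to a secant step
        # once two evaluations bracket the empirical response of the
        # alignment statistic to b.
        slope = -dmz_db
        if b_prev is not None and abs(b - b_prev) > 1e-9 and delta != delta_prev:
            secant = (delta - delta_prev) / (b - b_prev)
            if secant < 0:
                slope = secant
        b_prev, delta_prev = b, delta
        b -= delta / slope
    match = score_spectra(experimental_centroids, sim_cen if sim_cen is not None else sim, scoring)
    return match.score, b, gap


def screen_ratios(
    experimental: Spectrum,
    model: AssemblyModel,
    instrument: InstrumentModel,
    scoring: ScoringConfig = ScoringConfig(),
    step: int = 1,
    coarse_to_fine: bool = False,
    fine_window: int = 5,
    min_rel_abundance: float = DEFAULT_MIN_REL_ABUNDANCE,
    mean_mode: str = "intensity",
) -> ScreenGrid:
    """Grid-search bulk VP percentages against a baseline-corrected spectrum.

    Parameters
    ----------
    experimental
        Baseline-corrected experimental (or pseudo-experimental) spectrum.
    model, instrument, scoring
        Assembly model (3 species), instrument settings (the charging
        offset is recalibrated per grid point) and scoring parameters.
    step
        Grid increment in percentage points (1 = the exhaustive 5,151-point
        screen; 5 = 231 points).
    coarse_to_fine
        If True, evaluate the coarse ``step`` grid first and then refine at
        step 1 within ``fine_window`` points of the coarse optimum.
    min_rel_abundance
        Per-point ensemble truncation threshold (relative to the modal
        stoichiometry probability); purely a speed optimization.
    mean_mode
        Alignment statistic used to place the simulated envelope on the
        experimental m/z region: ``"intensity"`` (default) aligns the
        bin-intensity-weighted means of the baseline-corrected spectra;
        ``"centroid"`` aligns the apex-weighted means of the detected
        peak centroids instead.  Because the simulated peak positions are
        a fixed comb M/z with integer z, the offset only places the
        intensity envelope on that comb; sub-charge accuracy is ample.

    Returns
    -------
    ScreenGrid
        Scores and calibrated offsets for every evaluated point.
    """
    if model.n_species != 3:
        raise ValueError("screening is defined for the 3-species model")
    centroids = detect_centroids(experimental, scoring)
    if len(centroids) < 3:
        raise ValueError(
            f"experimental spectrum has only {len(centroids)} detected peaks (>= 3 required); "
            "check baseline correction and the min_peak_rel_height threshold"
        )
    if mean_mode == "intensity":
        exp_stat = experimental.mean_mz()
    elif mean_mode == "centroid":
        exp_stat = _alignment_stat(centroids)
    else:
        raise ValueError("mean_mode must be 'intensity' or 'centroid'")

    scores = np.full((101, 101), np.nan)
    offsets = np.full((101, 101), np.nan)
    n_points = 0
    gap_hint = 0.0

    def run(points: list[tuple[int, int]]):
        nonlocal n_points, gap_hint
        for v1, v2 in points:
            if not np.isnan(scores[v1, v2]):
                continue
            s, b, gap_hint = _evaluate_point(
                v1, v2, centroids, exp_stat, model, instrument, scoring,
                min_rel_abundance, gap_hint, mean_mode,
            )
            scores[v1, v2] = s
            offsets[v1, v2] = b
            n_points += 1
            logger.debug("screen point vp1=%d vp2=%d score=%.6f b=%.3f", v1, v2, s, b)

    run(_grid_points(step))
    if coarse_to_fine and step > 1:
        grid = ScreenGrid(step, scores, offsets, n_points)
        v1c, v2c, _, _ = best_ratio(grid, as_indices=True)
        fine = [
            (v1, v2)
            for v1 in range(max(0, v1c - fine_window), min(100, v1c + fine_window) + 1)
            for v2 in range(max(0, v2c - fine_window), min(100 - v1, v2c + fine_window) + 1)
        ]
        run(fine)
    return ScreenGrid(step, scores, offsets, n_points)


def best_ratio(grid: ScreenGrid, as_indices: bool = False):
    """Best-scoring grid point; ties broken by lowest VP1% then lowest VP2%.

    Returns ``(VPRatio, score, offset_b)`` or, with ``as_indices=True``,
    ``(vp1_percent, vp2_percent, score, offset_b)``.
    """
    if not grid.evaluated().any():
        raise ValueError("empty screen grid")
    best = np.nanmax(grid.scores)
    v1, v2 = [int(a[0]) for a in np.nonzero(grid.scores == best)]
    # np.nonzero scans row-major, so the first hit already realizes the
    # lowest-vp1-then-lowest-vp2 tie-break.
    if as_indices:
        return v1, v2, float(best), float(grid.offsets[v1, v2])
    return VPRatio(v1, v2, 100 - v1 - v2), float(best), float(grid.offsets[v1, v2])
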