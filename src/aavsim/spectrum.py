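"""Mass-spectrum container and plain-text / mzML input-output.

A :class:`Spectrum` is a uniform m/z axis (Thomson) with nonnegative
intensities and a free-form metadata dict recording provenance (simulated
vs experimental, instrument settings, seeds).  The native text format is
two whitespace-separated columns (m/z, intensity) preceded by ``#``-prefixed
``key: value`` header lines; experimental data can also be read from mzML.
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np

__all__ = ["Spectrum"]

_AXIS_RTOL = 1e-6


class Spectrum:
    """Uniformly gridded mass spectrum.

    Parameters
    ----------
    mz : array
        Strictly increasing, uniformly spaced m/z axis in Thomson.
    intensity : array
        Nonnegative intensity per bin, same length as ``mz``.
    metadata : dict, optional
        Provenance information; written to / read from the file header.
    """

    def __init__(self, mz, intensity, metadata: dict | None = None):
        mz = np.asarray(mz, dtype=float)
        intensity = np.asarray(intensity, dtype=float)
        if mz.ndim != 1 or mz.size < 2:
            raise ValueError("mz axis must be 1-D with at least two points")
        if intensity.shape != mz.shape:
            raise ValueError("mz and intensity must have the same shape")
        steps = np.diff(mz)
        if steps[0] <= 0 or not np.allclose(steps, steps[0], rtol=_AXIS_RTOL, atol=0):
            raise ValueError("mz axis must be strictly increasing and uniform")
        if np.any(intensity < 0):
            raise ValueError("intensities must be nonnegative")
        self.mz = mz
        self.intensity = intensity
        self.metadata = dict(metadata or {})

    # -- basic properties -------------------------------------------------

    @property
    def step(self) -> float:
        return float(self.mz[1] - self.mz[0])

    def __len__(self) -> int:
        return self.mz.size

    def copy(self) -> "Spectrum":
        return Spectrum(self.mz.copy(), self.intensity.copy(), dict(self.metadata))

    def mean_mz(self) -> float:
        """Intensity-weighted mean m/z position of the spectrum."""
        total = self.intensity.sum()
        if total <= 0:
            raise ValueError("cannot take the mean m/z of an all-zero spectrum")
        return float(np.dot(self.mz, self.intensity) / total)

    def max_normalized(self) -> "Spectrum":
        """Copy scaled so the most intense bin equals 1 (no-op if all zero)."""
        out = self.copy()
        peak = out.intensity.max()
        if peak > 0:
            out.intensity /= peak
        return out

    # -- text IO ----------------------------------------------------------

    def save_text(self, path) -> None:
        """Write the two-column text format with a ``#`` metadata header."""
        with open(path, "w") as fh:
            for key, value in self.metadata.items():
                fh.write(f"# {key}: {value}\n")
            np.savetxt(fh, np.column_stack([self.mz, self.intensity]), fmt="%.6f\t%.8e")

    @classmethod
    def load_text(cls, path) -> "Spectrum":
        """Read the two-column text format (``#`` header lines optional)."""
        metadata = {}
        rows = []
        path = Path(path)
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    body = line.lstrip("#").strip()
                    if ":" in body:
                        key, _, value = body.partition(":")
                        metadata[key.strip()] = value.strip()
                    continue
                parts = line.split()
                if len(parts) < 2:
                    raise ValueError(f"{path}, line {lineno}: expected two columns, got {line!r}")
                try:
                    rows.append((float(parts[0]), float(parts[1])))
                except ValueError as exc:
                    raise ValueError(f"{path}, line {lineno}: non-numeric value in {line!r}") from exc
        if len(rows) < 2:
            raise ValueError(f"{path}: fewer than two data rows")
        arr = np.array(rows)
        return cls(arr[:, 0], np.clip(arr[:, 1], 0.0, None), metadata)

    # -- mzML IO ----------------------------------------------------------

    @classmethod
    def from_mzml(cls, path, grid_step: float | None = None) -> "Spectrum":
        """Read an mzML file, summing all MS1 scans onto one uniform grid.

        Profile or centroided scans are both accepted; intensities are
        binned onto a uniform axis with spacing ``grid_step`` (default: the
        median spacing of the first scan).  The reader handles the standard
        binary encodings (32/64-bit float, optional zlib compression).
        """
        mzs, ints = [], []
        for scan_mz, scan_int in _iter_mzml_scans(path):
            mzs.append(scan_mz)
            ints.append(scan_int)
        if not mzs:
            raise ValueError(f"{path}: no MS1 spectra found")
        if grid_step is None:
            grid_step = float(np.median(np.diff(mzs[0]))) if mzs[0].size > 1 else 1.0
        lo = min(m.min() for m in mzs)
        hi = max(m.max() for m in mzs)
        grid = np.arange(lo, hi + grid_step / 2, grid_step)
        total = np.zeros(grid.size)
        for m, i in zip(mzs, ints):
            idx = np.clip(np.round((m - lo) / grid_step).astype(int), 0, grid.size - 1)
            np.add.at(total, idx, i)
        return cls(grid, total, {"source": "experimental", "file": str(path)})

    def __repr__(self) -> str:
        return (
            f"Spectrum({self.mz[0]:.1f}-{self.mz[-1]:.1f} Th, "
            f"{len(self)} bins, step {self.step:.3g} Th)"
        )


# PSI-MS controlled-vocabulary accessions for binary-data decoding.
_CV_MZ_ARRAY = "MS:1000514"
_CV_INTENSITY_ARRAY = "MS:1000515"
_CV_FLOAT64 = "MS:1000523"
_CV_FLOAT32 = "MS:1000521"
_CV_ZLIB = "MS:1000574"
_CV_MS_LEVEL = "MS:1000511"


def _iter_mzml_scans(path):
    """Yield (mz, intensity) arrays for each MS1 spectrum of an mzML file.

    A deliberately small reader covering the universal subset of the
    format: uncompressed or zlib-compressed 32/64-bit float arrays.
    """
    import base64
    import xml.etree.ElementTree as ET
    import zlib

    def local(tag):
        return tag.rsplit("}", 1)[-1]

    for _, spectrum in ET.iterparse(str(path)):
        if local(spectrum.tag) != "spectrum":
            continue
        cv = {}
        arrays = {}
        for elem in spectrum.iter():
            if local(elem.tag) == "cvParam" and elem.get("accession"):
                cv.setdefault(elem.get("accession"), elem.get("value", ""))
        for bda in spectrum.iter():
            if local(bda.tag) != "binaryDataArray":
                continue
            accs = {e.get("accession") for e in bda.iter() if local(e.tag) == "cvParam"}
            binary = next((e for e in bda.iter() if local(e.tag) == "binary"), None)
            if binary is None or binary.text is None:
                continue
            raw = base64.b64decode(binary.text.strip())
            if _CV_ZLIB in accs:
                raw = zlib.decompress(raw)
            dtype = "<f4" if _CV_FLOAT32 in accs else "<f8"
            data = np.frombuffer(raw, dtype=dtype).astype(float)
            if _CV_MZ_ARRAY in accs:
                arrays["mz"] = data
            elif _CV_INTENSITY_ARRAY in accs:
                arrays["intensity"] = data
        ms_level = int(cv.get(_CV_MS_LEVEL) or 1)
        if ms_level == 1 and "mz" in arrays and "intensity" in arrays:
            yield arrays["mz"], arrays["intensity"]
        spectrum.clear()
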