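"""Peak-list ("File 1") and per-peak metadata ("File 2") handling.

Both files are tab-separated text with a header line.  File 1 holds one
row per mass signal: a unique ID, a mass (neutral, or m/z with a
recorded polarity, free of adducts), and one intensity column per
sample.  File 2 carries arbitrary extra columns (retention time,
p-values, ...) for the same IDs in the same order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PeakList",
    "load_peaklist",
    "write_peaklist",
    "load_metadata",
    "PeakListParseError",
    "POLARITIES",
    "HIGH_MASS_WARNING_DA",
]

logger = logging.getLogger("pepnet")

POLARITIES = ("neutral", "positive", "negative")

#: masses above this are accepted but flagged; decomposition ambiguity
#: grows quickly with mass, so annotations up there are rarely unique
HIGH_MASS_WARNING_DA = 1600.0

#: below this sample count, correlations between network nodes are noisy
MIN_RECOMMENDED_SAMPLES = 10


class PeakListParseError(ValueError):
    """Raised for malformed File 1 / File 2 input."""


@dataclass
class PeakList:
    """A peak list: IDs, masses and a peaks x samples intensity matrix."""

    ids: list[str]
    masses: np.ndarray
    intensities: pd.DataFrame  # index = ids, columns = sample names
    polarity: str = "neutral"
    source: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.polarity not in POLARITIES:
            raise ValueError(f"polarity must be one of {POLARITIES}")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("peak IDs must be unique")
        self.masses = np.asarray(self.masses, dtype=float)
        if not (len(self.ids) == len(self.masses) == len(self.intensities)):
            raise ValueError("ids, masses and intensity rows must align")
        if self.intensities.shape[1] < 1:
            raise ValueError("at least one sample (intensity column) required")
        if (self.intensities.to_numpy() < 0).any():
            raise ValueError("intensities must be non-negative")
        self.intensities = self.intensities.set_axis(self.ids, axis=0)

    @property
    def n_peaks(self) -> int:
        return len(self.ids)

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[1]

    @property
    def samples(self) -> list[str]:
        return list(self.intensities.columns)

    def mass_of(self, peak_id: str) -> float:
        return float(self.masses[self.ids.index(peak_id)])

    def intensity_of(self, peak_id: str) -> np.ndarray:
        return self.intensities.loc[peak_id].to_numpy(dtype=float)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"ID": self.ids, "mass": self.masses})
        return pd.concat([df, self.intensities.reset_index(drop=True)], axis=1)


def _split_rows(path: Path) -> tuple[list[str], list[tuple[int, list[str]]]]:
    lines = path.read_text().splitlines()
    rows = [(i + 1, ln.split("\t")) for i, ln in enumerate(lines) if ln.strip()]
    if len(rows) < 2:
        raise PeakListParseError(f"{path}: need a header line and at least one row")
    header = [h.strip() for h in rows[0][1]]
    return header, rows[1:]


def load_peaklist(path: str | Path, polarity: str = "neutral") -> PeakList:
    """Parse a tab-separated File 1 into a validated :class:`PeakList`.

    Columns are ID, mass, then one or more intensity columns.  Missing
    intensity cells are read as 0.  Masses above 1 600 Da and sample
    counts below 10 are logged as warnings, never errors.
    """
    path = Path(path)
    header, rows = _split_rows(path)
    if len(header) < 3:
        raise PeakListParseError(
            f"{path}: expected at least 3 columns (ID, mass, intensity), "
            f"got {len(header)}"
        )
    sample_names = header[2:]
    width = len(header)

    ids: list[str] = []
    seen: set[str] = set()
    masses: list[float] = []
    intensities: list[list[float]] = []
    for lineno, parts in rows:
        if len(parts) != width:
            raise PeakListParseError(
                f"{path}:{lineno}: expected {width} columns, got {len(parts)}"
            )
        pid = parts[0].strip()
        if not pid:
            raise PeakListParseError(f"{path}:{lineno}: empty peak ID")
        if pid in seen:
            raise PeakListParseError(f"{path}:{lineno}: duplicate peak ID {pid!r}")
        seen.add(pid)
        try:
            mass = float(parts[1])
        except ValueError:
            raise PeakListParseError(
                f"{path}:{lineno}: non-numeric mass {parts[1]!r}"
            ) from None
        row: list[float] = []
        for j, cell in enumerate(parts[2:]):
            cell = cell.strip()
            if cell in ("", "NA", "nan", "NaN"):
                row.append(0.0)  # absence encoded as zero
                continue
            try:
                row.append(float(cell))
            except ValueError:
                raise PeakListParseError(
                    f"{path}:{lineno}: non-numeric intensity {cell!r} "
                    f"in column {sample_names[j]!r}"
                ) from None
        ids.append(pid)
        masses.append(mass)
        intensities.append(row)

    mass_arr = np.array(masses)
    if (mass_arr > HIGH_MASS_WARNING_DA).any():
        n_high = int((mass_arr > HIGH_MASS_WARNING_DA).sum())
        logger.warning(
            "%s: %d mass(es) above %.0f Da; decomposition is not recommended "
            "that high",
            path,
            n_high,
            HIGH_MASS_WARNING_DA,
        )
    if len(sample_names) < MIN_RECOMMENDED_SAMPLES:
        logger.warning(
            "%s: only %d sample column(s); at least %d are recommended for "
            "reliable node correlations",
            path,
            len(sample_names),
            MIN_RECOMMENDED_SAMPLES,
        )
    frame = pd.DataFrame(intensities, columns=sample_names)
    return PeakList(ids, mass_arr, frame, polarity, source=str(path))


def write_peaklist(peaks: PeakList, path: str | Path, decimals: int = 6) -> None:
    """Write a peak list back out in File 1 format."""
    lines = ["\t".join(["ID", "mass"] + peaks.samples)]
    mat = peaks.intensities.to_numpy()
    for i, pid in enumerate(peaks.ids):
        cells = [pid, f"{peaks.masses[i]:.{decimals}f}"]
        cells += [np.format_float_positional(v, trim="0") for v in mat[i]]
        lines.append("\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


def load_metadata(path: str | Path, peaks: PeakList) -> pd.DataFrame:
    """Parse File 2 and align it against ``peaks``.

    The first column must repeat the peak IDs of File 1 in identical
    order; any mismatch is an error naming the first offending ID.
    """
    path = Path(path)
    header, rows = _split_rows(path)
    width = len(header)
    ids: list[str] = []
    records: list[list[str]] = []
    for lineno, parts in rows:
        if len(parts) != width:
            raise PeakListParseError(
                f"{path}:{lineno}: expected {width} columns, got {len(parts)}"
            )
        ids.append(parts[0].strip())
        records.append([p.strip() for p in parts[1:]])

    if len(ids) != peaks.n_peaks:
        raise PeakListParseError(
            f"{path}: {len(ids)} rows but the peak list has {peaks.n_peaks}"
        )
    for i, (got, want) in enumerate(zip(ids, peaks.ids)):
        if got != want:
            raise PeakListParseError(
                f"{path}: metadata ID {got!r} at row {i + 1} does not match "
                f"peak ID {want!r}; File 2 must repeat File 1 IDs in order"
            )
    df = pd.DataFrame(records, columns=header[1:], index=ids)
    # keep numeric columns numeric (retention times, p-values, scores)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        if not converted.isna().any() or (df[col] == "").all():
            df[col] = converted
    return df
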