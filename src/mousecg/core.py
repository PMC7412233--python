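"""Core domain types, Einthoven/Goldberger lead algebra, and record I/O.

The central container is :class:`ECGRecord`: a multi-lead amplitude matrix
(mV) with a sample rate in Hz and ordered lead labels.  Beat positions are
carried as :class:`BeatAnnotations` (strictly increasing sample indices) and
inter-beat timing as :class:`RRSeries` (consecutive R-to-R intervals in ms,
each anchored to the sample index of its terminating peak).

Sample indices are 0-based throughout; time intervals are half-open
``[start, end)``.  Amplitudes are always millivolts — readers reject files
that declare any other unit.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ECGRecord",
    "BeatAnnotations",
    "RRSeries",
    "read_record",
    "write_record",
    "read_annotations",
    "write_annotations",
    "derive_lead_iii",
    "derive_augmented_leads",
    "segment_record",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ECGRecord:
    """Multi-lead ECG time series.

    Parameters
    ----------
    signals
        Array of shape ``(n_leads, n_samples)`` holding amplitudes in mV.
    sample_rate
        Sampling frequency in Hz; must be positive.
    lead_labels
        Ordered lead names, one per row of ``signals`` (e.g. ``["I", "II",
        "III"]``).
    start_time
        Offset in seconds of the first sample relative to the start of the
        parent recording (nonzero for fragments produced by
        :func:`segment_record`).
    partial
        True for a trailing fragment shorter than the requested length.
    """

    signals: np.ndarray
    sample_rate: float
    lead_labels: list[str]
    start_time: float = 0.0
    partial: bool = False

    def __post_init__(self) -> None:
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=float))
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        self.lead_labels = list(self.lead_labels)
        if len(self.lead_labels) != self.signals.shape[0]:
            raise ValueError(
                f"{len(self.lead_labels)} lead labels for "
                f"{self.signals.shape[0]} signal rows"
            )

    @property
    def n_leads(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    def lead(self, label: str) -> np.ndarray:
        """Return the signal of the lead named `label`."""
        try:
            return self.signals[self.lead_labels.index(label)]
        except ValueError:
            raise KeyError(
                f"lead {label!r} not in record (have {self.lead_labels})"
            ) from None


@dataclass
class BeatAnnotations:
    """Ordered R-peak sample indices with provenance.

    ``source`` distinguishes automatically ``"detected"`` peaks from manually
    curated ``"reference"`` annotations used for detector evaluation.
    """

    peak_indices: np.ndarray
    source: str
    sample_rate: float

    def __post_init__(self) -> None:
        self.peak_indices = np.asarray(self.peak_indices, dtype=np.int64)
        if self.source not in ("detected", "reference"):
            raise ValueError("source must be 'detected' or 'reference'")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.peak_indices.ndim != 1:
            raise ValueError("peak_indices must be one-dimensional")
        if len(self.peak_indices) > 1 and np.any(np.diff(self.peak_indices) <= 0):
            raise ValueError("peak indices must be strictly increasing")
        if len(self.peak_indices) and self.peak_indices[0] < 0:
            raise ValueError("peak indices must be non-negative")

    def __len__(self) -> int:
        return len(self.peak_indices)

    @property
    def times_s(self) -> np.ndarray:
        """Peak times in seconds from record start."""
        return self.peak_indices / self.sample_rate


@dataclass
class RRSeries:
    """Consecutive R-to-R intervals in milliseconds.

    ``anchor_indices`` holds, for each interval, the sample index of the
    *terminating* peak of the pair, so intervals stay aligned with the beats
    they end on (one interval fewer than there are peaks).
    """

    intervals_ms: np.ndarray
    anchor_indices: np.ndarray = field(default=None)  # type: ignore[assignment]
    sample_rate: float = float("nan")

    def __post_init__(self) -> None:
        self.intervals_ms = np.asarray(self.intervals_ms, dtype=float)
        if self.anchor_indices is None:
            self.anchor_indices = np.zeros(len(self.intervals_ms), dtype=np.int64)
        self.anchor_indices = np.asarray(self.anchor_indices, dtype=np.int64)
        if len(self.anchor_indices) != len(self.intervals_ms):
            raise ValueError("anchor_indices must align 1:1 with intervals")
        if len(self.intervals_ms) and np.any(self.intervals_ms <= 0):
            raise ValueError("all RR intervals must be positive")

    def __len__(self) -> int:
        return len(self.intervals_ms)

    @property
    def mean_ms(self) -> float:
        return float(np.mean(self.intervals_ms)) if len(self) else float("nan")


# ---------------------------------------------------------------------------
# Lead algebra (Einthoven / Goldberger)
# ---------------------------------------------------------------------------

def _check_equal_length(lead_i: np.ndarray, lead_ii: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lead_i = np.asarray(lead_i, dtype=float)
    lead_ii = np.asarray(lead_ii, dtype=float)
    if lead_i.shape != lead_ii.shape:
        raise ValueError(
            f"lead length mismatch: {lead_i.shape} vs {lead_ii.shape}"
        )
    return lead_i, lead_ii


def derive_lead_iii(lead_i: np.ndarray, lead_ii: np.ndarray) -> np.ndarray:
    """Einthoven's second law: III = II − I (clinical polarity)."""
    lead_i, lead_ii = _check_equal_length(lead_i, lead_ii)
    return lead_ii - lead_i


def derive_augmented_leads(
    lead_i: np.ndarray, lead_ii: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Goldberger augmented limb leads (aVR, aVL, aVF) from leads I and II.

    aVR = −(I + II)/2, aVL = I − II/2, aVF = II − I/2; their sum is
    identically zero.
    """
    lead_i, lead_ii = _check_equal_length(lead_i, lead_ii)
    avr = -(lead_i + lead_ii) / 2.0
    avl = lead_i - lead_ii / 2.0
    avf = lead_ii - lead_i / 2.0
    return avr, avl, avf


# ---------------------------------------------------------------------------
# Record I/O — delimited text with a small comment header
# ---------------------------------------------------------------------------
#
# Format: '#'-prefixed header lines carrying `sample_rate_hz=`, `leads=`
# and optional `unit=` / `start_time_s=` keys, followed by one whitespace- or
# comma-delimited column per lead.

def write_record(record: ECGRecord, path) -> None:
    """Write `record` as delimited text (one column per lead, mV)."""
    header = (
        f"# sample_rate_hz={record.sample_rate:g}\n"
        f"# leads={','.join(record.lead_labels)}\n"
        f"# unit=mV\n"
        f"# start_time_s={record.start_time:g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, record.signals.T, fmt="%.6f", delimiter="\t")


def read_record(path, format: str = "delimited") -> ECGRecord:
    """Read an ECG record from disk.

    Only the delimited-text format is supported: '#'-comment header lines
    declaring ``sample_rate_hz`` and ``leads``, then one amplitude column per
    lead.  Amplitudes must be in mV (files declaring another unit are
    rejected rather than silently rescaled).
    """
    if format != "delimited":
        raise ValueError(f"unsupported record format: {format!r}")
    meta: dict[str, str] = {}
    body = io.StringIO()
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                stripped = line.lstrip("#").strip()
                if "=" in stripped:
                    key, _, value = stripped.partition("=")
                    meta[key.strip()] = value.strip()
            else:
                body.write(line)
    if "sample_rate_hz" not in meta:
        raise ValueError(f"{path}: missing 'sample_rate_hz' header")
    unit = meta.get("unit", "mV")
    if unit.lower() != "mv":
        raise ValueError(f"{path}: amplitudes must be in mV, got {unit!r}")
    body.seek(0)
    first_data = body.readline()
    body.seek(0)
    delimiter = "," if "," in first_data else None
    try:
        data = np.loadtxt(body, delimiter=delimiter, ndmin=2)
    except ValueError as exc:
        # np.loadtxt raises on ragged rows and non-numeric content alike;
        # distinguish for a clearer message.
        msg = str(exc)
        if "could not convert" in msg or "could not be read" in msg:
            raise ValueError(f"{path}: non-numeric content") from exc
        raise ValueError(f"{path}: ragged channels (rows of unequal width)") from exc
    sample_rate = float(meta["sample_rate_hz"])
    labels = (
        [s.strip() for s in meta["leads"].split(",")]
        if "leads" in meta
        else [f"ch{i}" for i in range(data.shape[1])]
    )
    if len(labels) != data.shape[1]:
        raise ValueError(
            f"{path}: header declares {len(labels)} leads but file has "
            f"{data.shape[1]} columns"
        )
    return ECGRecord(
        signals=data.T,
        sample_rate=sample_rate,
        lead_labels=labels,
        start_time=float(meta.get("start_time_s", 0.0)),
    )


def write_annotations(annotations: BeatAnnotations, path) -> None:
    """Write beat annotations as single-column text of sample indices."""
    with open(path, "w") as fh:
        fh.write(f"# sample_rate_hz={annotations.sample_rate:g}\n")
        fh.write(f"# source={annotations.source}\n")
        for idx in annotations.peak_indices:
            fh.write(f"{idx}\n")


def read_annotations(
    path, sample_rate: float | None = None, source: str = "reference"
) -> BeatAnnotations:
    """Read single-column sample-index annotations.

    A ``# sample_rate_hz=`` header, if present, overrides the `sample_rate`
    argument; one of the two must supply the rate.
    """
    meta: dict[str, str] = {}
    indices: list[int] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                stripped = line.lstrip("#").strip()
                if "=" in stripped:
                    key, _, value = stripped.partition("=")
                    meta[key.strip()] = value.strip()
                continue
            indices.append(int(float(line)))
    rate = float(meta.get("sample_rate_hz", sample_rate or 0))
    if rate <= 0:
        raise ValueError(f"{path}: no sample rate in header or arguments")
    return BeatAnnotations(
        peak_indices=np.asarray(indices, dtype=np.int64),
        source=meta.get("source", source),
        sample_rate=rate,
    )


# ---------------------------------------------------------------------------
# Segmentation into fixed-length fragments
# ---------------------------------------------------------------------------

def segment_record(record: ECGRecord, fragment_s: float = 1200.0) -> list[ECGRecord]:
    """Cut `record` into consecutive non-overlapping fragments.

    The default fragment length is 20 minutes, the unit in which long
    ambulatory recordings are batch-processed.  A trailing fragment shorter
    than `fragment_s` is kept and flagged ``partial`` so that downstream
    heart-rate normalisation can use its true duration; concatenating the
    fragments reproduces the input exactly.
    """
    if fragment_s <= 0:
        raise ValueError("fragment_s must be positive")
    step = int(round(fragment_s * record.sample_rate))
    fragments: list[ECGRecord] = []
    for start in range(0, record.n_samples, step):
        stop = min(start + step, record.n_samples)
        fragments.append(
            replace(
                record,
                signals=record.signals[:, start:stop].copy(),
                start_time=record.start_time + start / record.sample_rate,
                partial=(stop - start) < step,
            )
        )
    return fragments
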