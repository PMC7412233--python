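"""Semi-automatic ectopic-beat flagging with ROI export for manual review.

An ectopic beat (premature atrial or ventricular complex, sinus arrest,
blocked P wave) perturbs the local R-to-R rhythm.  The detector compares
each RR interval against a moving average over a 100-interval sliding
window, centred on the interval and excluding the interval itself so that
an aberrant interval cannot pollute its own reference.  Intervals deviating
from that local average by more than a threshold (default 30%) are flagged.

Flagging is deliberately only the first half of the workflow: each flag is
exported as a region of interest (ROI) — a short window of the band-passed
trace around the beat, plus a machine-readable table — for manual
classification on the original unfiltered trace.  Consecutive flagged
intervals that share a beat (the premature interval and its compensatory
pause) are merged into one ROI so a single event is reported once.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import BeatAnnotations, ECGRecord, RRSeries

__all__ = [
    "EctopicConfig",
    "EctopicROI",
    "moving_average_rr",
    "flag_ectopic",
    "export_rois",
]


@dataclass
class EctopicConfig:
    window_intervals: int = 100
    deviation_threshold: float = 0.30
    roi_halfwidth_ms: float = 500.0

    def __post_init__(self) -> None:
        if self.window_intervals < 2:
            raise ValueError("window_intervals must be at least 2")
        if not 0.0 < self.deviation_threshold < 1.0:
            raise ValueError("deviation_threshold must be in (0, 1)")
        if self.roi_halfwidth_ms <= 0:
            raise ValueError("roi_halfwidth_ms must be positive")


@dataclass
class EctopicROI:
    """One flagged beat with its context window.

    ``beat_index`` is the sample index of the terminating peak of the
    deviating interval; ``window_start_s``/``window_end_s`` bound the review
    window (clipped to the record).
    """

    beat_index: int
    interval_ms: float
    moving_avg_ms: float
    deviation_fraction: float
    window_start_s: float
    window_end_s: float


def moving_average_rr(rr: RRSeries, window: int = 100) -> np.ndarray:
    """Centred moving average of the RR series, excluding the centre value.

    For interval *i* the reference is the mean of up to ``window`` intervals
    in ``[i − window//2, i + window//2]`` clipped to the series, with
    interval *i* itself excluded.  Defined for every index of any series of
    length ≥ 2.
    """
    x = np.asarray(rr.intervals_ms, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 intervals for a moving average")
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(x)])
    i = np.arange(n)
    lo = np.maximum(i - half, 0)
    hi = np.minimum(i + half, n - 1)
    total = csum[hi + 1] - csum[lo]
    count = hi - lo + 1
    return (total - x) / (count - 1)


def flag_ectopic(rr: RRSeries, config: EctopicConfig | None = None) -> list[EctopicROI]:
    """Flag intervals deviating from the local moving average.

    An interval is flagged when |RR − MA| / MA exceeds the configured
    threshold.  Runs of consecutive flagged intervals collapse into a single
    ROI anchored on the most deviant interval of the run, with the review
    window spanning the whole run.
    """
    config = config or EctopicConfig()
    if len(rr) < 2:
        return []
    ma = moving_average_rr(rr, config.window_intervals)
    deviation = np.abs(rr.intervals_ms - ma) / ma
    flagged = np.nonzero(deviation > config.deviation_threshold)[0]
    if len(flagged) == 0:
        return []
    fs = rr.sample_rate
    half_s = config.roi_halfwidth_ms / 1000.0
    rois: list[EctopicROI] = []
    run = [flagged[0]]
    runs = []
    for i in flagged[1:]:
        if i == run[-1] + 1:
            run.append(i)
        else:
            runs.append(run)
            run = [i]
    runs.append(run)
    for run in runs:
        run = np.asarray(run)
        anchor = run[int(np.argmax(deviation[run]))]
        t_first = rr.anchor_indices[run[0]] / fs
        t_last = rr.anchor_indices[run[-1]] / fs
        rois.append(
            EctopicROI(
                beat_index=int(rr.anchor_indices[anchor]),
                interval_ms=float(rr.intervals_ms[anchor]),
                moving_avg_ms=float(ma[anchor]),
                deviation_fraction=float(deviation[anchor]),
                window_start_s=t_first - half_s,
                window_end_s=t_last + half_s,
            )
        )
    return rois


ROI_CSV_COLUMNS = [
    "beat_index",
    "time_s",
    "interval_ms",
    "moving_avg_ms",
    "deviation_fraction",
]


def export_rois(
    record: ECGRecord,
    rois: list[EctopicROI],
    annotations: BeatAnnotations,
    out_dir,
    lead: str | None = None,
    basename: str = "ectopic_rois",
) -> dict[str, Path]:
    """Write the ROI review document (multi-page PDF) and CSV table.

    Each ROI becomes one page plotting the trace around the flagged beat
    with all detected peaks marked; windows are clipped to the record
    bounds.  With zero ROIs only the CSV (header row) is written.  Returns
    the paths actually written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fs = record.sample_rate
    csv_path = out_dir / f"{basename}.csv"
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(ROI_CSV_COLUMNS)
        for roi in rois:
            writer.writerow(
                [
                    roi.beat_index,
                    f"{roi.beat_index / fs:.4f}",
                    f"{roi.interval_ms:.3f}",
                    f"{roi.moving_avg_ms:.3f}",
                    f"{roi.deviation_fraction:.4f}",
                ]
            )
    written = {"csv": csv_path}
    if not rois:
        return written

    # Matplotlib is imported lazily so array-only workflows never touch it.
    from matplotlib.backends.backend_pdf import PdfPages
    from matplotlib.figure import Figure

    trace = record.lead(lead) if lead else record.signals[0]
    label = lead or record.lead_labels[0]
    pdf_path = out_dir / f"{basename}.pdf"
    with PdfPages(pdf_path) as pdf:
        for roi in rois:
            lo = max(int(roi.window_start_s * fs), 0)
            hi = min(int(roi.window_end_s * fs) + 1, record.n_samples)
            t = np.arange(lo, hi) / fs
            fig = Figure(figsize=(8, 3))
            ax = fig.add_subplot(111)
            ax.plot(t, trace[lo:hi], lw=0.8, color="k")
            in_win = (annotations.peak_indices >= lo) & (annotations.peak_indices < hi)
            peaks = annotations.peak_indices[in_win]
            ax.plot(peaks / fs, trace[peaks], "o", ms=4, color="tab:blue")
            ax.axvline(roi.beat_index / fs, color="tab:red", lw=0.8, ls="--")
            ax.set_xlabel("time (s)")
            ax.set_ylabel(f"lead {label} (mV)")
            ax.set_title(
                f"beat @ {roi.beat_index / fs:.3f} s — RR {roi.interval_ms:.1f} ms, "
                f"local mean {roi.moving_avg_ms:.1f} ms, "
                f"deviation {100 * roi.deviation_fraction:.0f}%"
            )
            fig.tight_layout()
            pdf.savefig(fig)
    written["pdf"] = pdf_path
    return written
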