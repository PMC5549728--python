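"""Electric-field detachment statistics and sliding along the polymer.

The in-silico electrophoresis assay pulls the polyanionic ligand off the
receptor with a uniform electric field and scores each replica by the
first frame at which the ligand-receptor atom-pair contact count reaches
zero — the ligand is then "detached"; replicas that never reach zero are
censored at the simulation end.  Summaries report the detachment fraction
and the mean detachment time +/- SE over the detached replicas only, with
an N/A sentinel where fewer than two replicas detached.

Receptor sliding along the polymer is tracked through the contact-count
centroid in monosaccharide index units: the contact-weighted mean polymer
position of the receptor per frame, interpolated across short zero-contact
gaps (binding along the chain is punctuated by transient partial
detachments).  Net displacement, maximum excursion and the mean squared
displacement per lag quantify the one-dimensional diffusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .contacts import ContactContour, ContactCountSeries, ResidueContactSeries, _mean_se
from .errors import ConfigError, DataError, GridRangeError, SchemaError


@dataclass
class DetachmentRecord:
    """Outcome of one detachment replica."""

    replica: int
    detached: bool
    time_ns: float | None         # first zero-contact time; None if censored
    censoring_time_ns: float
    field_tag: str = ""

    def __post_init__(self) -> None:
        if self.detached:
            if self.time_ns is None or self.time_ns > self.censoring_time_ns:
                raise DataError("detached record needs time <= censoring time")
        elif self.time_ns is not None:
            raise DataError("censored record must not carry a detachment time")


@dataclass
class DetachmentSummary:
    """Aggregate detachment statistics for one (mode, field) group."""

    fraction_percent: float
    mean_time_ns: float | None    # None when nothing detached
    se_time_ns: float             # NaN sentinel when n_detached <= 1
    n_detached: int
    n_total: int
    field_tag: str = ""

    def row(self) -> dict:
        return {
            "field": self.field_tag,
            "detachments_percent": self.fraction_percent,
            "mean_detachment_time_ns":
                0.0 if self.mean_time_ns is None else self.mean_time_ns,
            "se_ns": self.se_time_ns,
            "n_detached": self.n_detached,
            "n_total": self.n_total,
        }


def detect_detachment(counts: ContactCountSeries, dt_ns: float,
                      censoring_time_ns: float, replica: int = 0,
                      field_tag: str = "",
                      persistence: int = 1) -> DetachmentRecord:
    """Score one replica by the first zero-contact frame.

    ``persistence`` frames of consecutive zero contacts are required
    (default 1: a single zero triggers detachment, re-binding afterwards is
    ignored).  The detachment time is frame-index * ``dt_ns``.
    """
    c = np.asarray(counts.counts)
    if c.size == 0:
        raise DataError("empty contact-count series")
    zero = (c == 0)
    if persistence > 1:
        kernel = np.ones(persistence, dtype=int)
        runs = np.convolve(zero.astype(int), kernel, mode="valid")
        hits = np.nonzero(runs == persistence)[0]
    else:
        hits = np.nonzero(zero)[0]
    if hits.size:
        return DetachmentRecord(replica=replica, detached=True,
                                time_ns=float(hits[0] * dt_ns),
                                censoring_time_ns=censoring_time_ns,
                                field_tag=field_tag)
    return DetachmentRecord(replica=replica, detached=False, time_ns=None,
                            censoring_time_ns=censoring_time_ns,
                            field_tag=field_tag)


def summarize_detachments(records: Sequence[DetachmentRecord]
                          ) -> DetachmentSummary:
    """Fraction of detached replicas and mean +/- SE of detachment times.

    Only detached replicas enter the time statistics; SE is the NaN
    sentinel ("N/A") when at most one replica detached.
    """
    if len(records) == 0:
        raise DataError("need at least one detachment record")
    tags = {r.field_tag for r in records}
    if len(tags) > 1:
        raise SchemaError(f"mixed field tags in one summary: {sorted(tags)}")
    times = np.array([r.time_ns for r in records if r.detached], dtype=float)
    n_det = times.size
    frac = 100.0 * n_det / len(records)
    if n_det == 0:
        mean, se = None, float("nan")
    else:
        m, s = _mean_se(times)
        mean, se = float(m), float(s)
    return DetachmentSummary(fraction_percent=frac, mean_time_ns=mean,
                             se_time_ns=se, n_detached=n_det,
                             n_total=len(records), field_tag=tags.pop())


def detachment_table(summaries: dict[str, DetachmentSummary]) -> pd.DataFrame:
    """Mode-keyed summaries as a report table (detachment-assay layout)."""
    rows = []
    for mode, s in summaries.items():
        row = {"binding_mode": mode, **s.row()}
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# sliding
# --------------------------------------------------------------------------

@dataclass
class PartialDetachmentEvent:
    """Interval where total contacts drop below the low-watermark while at
    least one retained-set residue stays bound throughout."""

    start_frame: int
    end_frame: int                # half-open
    retained_residues: tuple[int, ...]


@dataclass
class SlidingTrack:
    """Receptor position along the polymer over time."""

    times: np.ndarray                  # ps
    centroid: np.ndarray               # monosaccharide units, NaN where undefined
    total_contacts: np.ndarray
    net_displacement: float            # last defined - first defined centroid
    max_excursion: float               # max |centroid - centroid(t0)|
    events: list[PartialDetachmentEvent] = field(default_factory=list)

    def displacement_series(self) -> np.ndarray:
        defined = np.nonzero(np.isfinite(self.centroid))[0]
        if defined.size == 0:
            return np.full_like(self.centroid, np.nan)
        return self.centroid - self.centroid[defined[0]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ps": self.times,
                             "centroid_mono": self.centroid,
                             "total_contacts": self.total_contacts})


def contact_centroid(contour: ContactContour, frame: int) -> float:
    """Contact-count-weighted mean monosaccharide index at one frame.

    Returns NaN (not an exception) when the frame holds no contacts, so
    tracks tolerate gaps.
    """
    col = contour.matrix[:, frame]
    total = col.sum()
    if total == 0:
        return float("nan")
    return float(np.dot(contour.mono_indices, col) / total)


def sliding_track(contour: ContactContour, max_gap: int = 20) -> SlidingTrack:
    """Centroid track along the polymer with gap-tolerant interpolation.

    Zero-contact stretches of at most ``max_gap`` frames are linearly
    interpolated between the flanking bound frames; longer gaps stay
    undefined (NaN).
    """
    n = contour.matrix.shape[1]
    cent = np.array([contact_centroid(contour, f) for f in range(n)])
    total = contour.matrix.sum(axis=0)
    filled = cent.copy()
    defined = np.nonzero(np.isfinite(cent))[0]
    if defined.size:
        for a, b in zip(defined, defined[1:]):
            gap = b - a - 1
            if 0 < gap <= max_gap:
                filled[a + 1:b] = np.interp(np.arange(a + 1, b), [a, b],
                                            [cent[a], cent[b]])
        net = float(cent[defined[-1]] - cent[defined[0]])
        exc = float(np.nanmax(np.abs(filled - cent[defined[0]])))
    else:
        net, exc = float("nan"), float("nan")
    return SlidingTrack(times=contour.times, centroid=filled,
                        total_contacts=total, net_displacement=net,
                        max_excursion=exc)


def detect_partial_detachment(series: ResidueContactSeries,
                              counts: ContactCountSeries,
                              retained_set: Sequence[int] = tuple(range(108, 115)),
                              watermark_fraction: float = 0.25
                              ) -> list[PartialDetachmentEvent]:
    """Partial-detachment events.

    An event is a maximal interval where the total contact count falls
    below ``watermark_fraction`` x the track median while staying nonzero
    (all-zero means full detachment, a different outcome) and at least one
    retained-set residue (default: the hydrogen-bond network stretch
    108-114) is in contact for the whole interval.
    """
    retained = [r for r in retained_set if r in series.residues]
    if len(retained_set) == 0:
        raise ConfigError("retained set must not be empty")
    ret_idx = [int(np.nonzero(series.residues == r)[0][0]) for r in retained]
    c = np.asarray(counts.counts, dtype=float)
    if c.shape[0] != series.contacts.shape[0]:
        raise SchemaError("counts and residue series disagree in frames")
    watermark = watermark_fraction * np.median(c)
    low = (c < watermark) & (c > 0)
    retained_ok = series.contacts[:, ret_idx].any(axis=1) if ret_idx else \
        np.zeros(len(c), dtype=bool)
    qualifying = low & retained_ok
    events: list[PartialDetachmentEvent] = []
    i = 0
    while i < len(qualifying):
        if qualifying[i]:
            j = i
            while j < len(qualifying) and qualifying[j]:
                j += 1
            kept = tuple(int(series.residues[k]) for k in ret_idx
                         if series.contacts[i:j, k].all())
            if kept:
                events.append(PartialDetachmentEvent(i, j, kept))
            i = j
        else:
            i += 1
    return events


def msd_1d(track: SlidingTrack, max_lag: int) -> pd.DataFrame:
    """Mean squared displacement of the centroid per lag (frames).

    Averages over all time origins with a defined centroid at both ends of
    the lag; returns a DataFrame (lag, msd, n_pairs).
    """
    x = track.centroid
    n = len(x)
    defined = np.isfinite(x)
    if defined.sum() < 2:
        raise DataError("need at least two defined centroid frames")
    if max_lag >= n:
        raise GridRangeError(f"max_lag {max_lag} >= track length {n}")
    lags = np.arange(1, max_lag + 1)
    msd = np.empty(len(lags))
    npairs = np.empty(len(lags), dtype=int)
    for i, lag in enumerate(lags):
        d = x[lag:] - x[:-lag]
        ok = np.isfinite(d)
        npairs[i] = ok.sum()
        msd[i] = float(np.mean(d[ok] ** 2)) if npairs[i] else float("nan")
    return pd.DataFrame({"lag": lags, "msd": msd, "n_pairs": npairs})
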