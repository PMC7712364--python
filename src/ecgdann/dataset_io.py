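"""Record loading, AAMI beat-class mapping and the interpatient split.

The interpatient protocol trains on one group of patients (DS1, the
source domain) and tests on a disjoint group (DS2, the target domain),
so no beat of a test patient is ever seen with its label during
training.  Only the first five minutes of each DS2 record are exposed —
unlabeled — to the adaptation procedure.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from . import wfdb_io

#: MIT-BIH beat symbol -> AAMI class.  N: normal / bundle-branch block /
#: escape; S: supraventricular ectopic; V: ventricular ectopic; F: fusion
#: of ventricular and normal; Q: paced / unclassifiable (dropped downstream).
AAMI_MAP: dict[str, str] = {
    "N": "N", "L": "N", "R": "N", "e": "N", "j": "N",
    "A": "S", "a": "S", "J": "S", "S": "S",
    "V": "V", "E": "V",
    "F": "F",
    "/": "Q", "f": "Q", "Q": "Q",
}

AAMI_CLASSES = ("N", "S", "V", "F")

#: Conventional interpatient partition of the 48 MIT-BIH records: four
#: paced records excluded, the remainder split into two patient-disjoint
#: halves with comparable class mixes.
DS1_IDS = (
    "101", "106", "108", "109", "112", "114", "115", "116", "118", "119",
    "122", "124", "201", "203", "205", "207", "208", "209", "215", "220",
    "223", "230",
)
DS2_IDS = (
    "100", "103", "105", "111", "113", "117", "121", "123", "200", "202",
    "210", "212", "213", "214", "219", "221", "222", "228", "231", "232",
    "233", "234",
)
EXCLUDED_IDS = ("102", "104", "107", "217")


class MissingLeadError(KeyError):
    pass


class UnknownRecordError(KeyError):
    pass


@dataclass
class BeatRecord:
    """One annotated single-lead ECG record."""

    record_id: str
    fs: float
    signal: np.ndarray          # (n_samples,) physical amplitudes
    r_peaks: np.ndarray         # strictly increasing sample indices
    symbols: list[str]          # raw beat symbol per R peak

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        self.r_peaks = np.asarray(self.r_peaks, dtype=np.int64)
        if len(self.symbols) != self.r_peaks.size:
            raise ValueError("symbols and r_peaks must be the same length")
        if self.r_peaks.size:
            if np.any(np.diff(self.r_peaks) <= 0):
                raise ValueError("r_peaks must be strictly increasing")
            if self.r_peaks[0] < 0 or self.r_peaks[-1] >= self.signal.size:
                raise ValueError("r_peaks out of signal range")

    @property
    def aami_labels(self) -> list[str]:
        return [map_to_aami(s) for s in self.symbols]


@dataclass
class SplitSpec:
    """Patient-disjoint DS1/DS2 partition with exclusions."""

    ds1_ids: tuple[str, ...] = DS1_IDS
    ds2_ids: tuple[str, ...] = DS2_IDS
    excluded_ids: tuple[str, ...] = EXCLUDED_IDS
    target_train_seconds: float = 300.0

    def __post_init__(self) -> None:
        if set(self.ds1_ids) & set(self.ds2_ids):
            raise ValueError("DS1 and DS2 overlap")
        if set(self.excluded_ids) & (set(self.ds1_ids) | set(self.ds2_ids)):
            raise ValueError("excluded records appear in a split")


def map_to_aami(symbol: str) -> str:
    """Map a raw beat symbol to its AAMI class; unknown symbols -> Q."""
    return AAMI_MAP.get(symbol, "Q")


def load_record(path: str, lead: str = "MLII") -> BeatRecord:
    """Load a WFDB header/signal/annotation triple as a :class:`BeatRecord`.

    ``path`` is the record prefix (no extension).  Raises
    :class:`MissingLeadError` if the requested lead is not present and
    ``FileNotFoundError`` if any of the three files is missing.
    """
    if not os.path.exists(path + ".hea"):
        raise FileNotFoundError(path + ".hea")
    rec = wfdb_io.read_record(path)
    if lead not in rec["sig_names"]:
        raise MissingLeadError(
            f"record {rec['record_name']}: lead {lead!r} not in {rec['sig_names']}"
        )
    chan = rec["sig_names"].index(lead)
    r_peaks, symbols = wfdb_io.read_annotations(path)
    return BeatRecord(
        record_id=rec["record_name"],
        fs=rec["fs"],
        signal=rec["signal"][:, chan],
        r_peaks=r_peaks,
        symbols=symbols,
    )


@dataclass
class SplitResult:
    """Beat-level interpatient partition.

    ``source`` holds all DS1 records (labels available).  ``target_train``
    holds, per DS2 record, a boolean mask over its beats selecting those
    whose R peak falls in the first ``target_train_seconds`` (labels are
    withheld from training).  ``target_test`` is every DS2 beat.
    """

    source: list[BeatRecord] = field(default_factory=list)
    target: list[BeatRecord] = field(default_factory=list)
    target_train_mask: dict[str, np.ndarray] = field(default_factory=dict)


def interpatient_split(records: list[BeatRecord], spec: SplitSpec | None = None) -> SplitResult:
    """Partition records into source (DS1) and target (DS2) domains.

    Every record must belong to exactly one of DS1, DS2 or the excluded
    list; excluded records are dropped.  The target-train mask is
    half-open: a beat is in the adaptation set iff
    ``r_peak < fs * target_train_seconds``.
    """
    spec = spec or SplitSpec()
    out = SplitResult()
    ds1, ds2, excl = set(spec.ds1_ids), set(spec.ds2_ids), set(spec.excluded_ids)
    for rec in records:
        if rec.record_id in excl:
            continue
        if rec.record_id in ds1:
            out.source.append(rec)
        elif rec.record_id in ds2:
            out.target.append(rec)
            boundary = rec.fs * spec.target_train_seconds
            out.target_train_mask[rec.record_id] = rec.r_peaks < boundary
        else:
            raise UnknownRecordError(rec.record_id)
    return out
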