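"""Amplicon-based indel quantification for surrogate libraries.

Merged reads are demultiplexed to libraries by exact containment of the
library's spacer + scaffold, retained only if they also carry the edited
downstream linker signature ``GTTTGAAT``, and reduced to the surrogate
window between the scaffold and that linker.  Editing calls are purely
length based against the 37-bp surrogate reference:

* total editing efficiency (percent) = reads with window length != 37
  over all reads;
* deletions of 1-30 bp are windows of length 36 down to 7, insertions of
  1-10 bp are lengths 38 to 47; lengths outside [7, 47] count as edited
  for the efficiency but fall outside the indel size classes;
* the pool-level average indel fraction = in-window indel reads over all
  reads of the pool.

Background (synthesis/PCR/sequencing) variants are removed by
subtracting any non-reference window sequence also observed in the
matched unedited control sample.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

LINKER_SIGNATURE = "GTTTGAAT"
REF_LEN = 37
MIN_WINDOW = 7    # 30-bp deletion
MAX_WINDOW = 47   # 10-bp insertion
MAX_DEL = 30
MAX_INS = 10
DEFAULT_MIN_READS = 200


@dataclass
class LibraryDef:
    guide_id: str
    spacer: str
    scaffold: str
    seq37: str


@dataclass
class IndelProfile:
    """Per-library read-length histogram mapped to indel size classes."""

    total_reads: int
    unedited_reads: int
    deletions: np.ndarray   # sizes 1..30 at indices 0..29
    insertions: np.ndarray  # sizes 1..10 at indices 0..9
    out_of_window: int

    def __post_init__(self):
        assert self.total_reads == (self.unedited_reads + int(self.deletions.sum())
                                    + int(self.insertions.sum()) + self.out_of_window)

    @property
    def edited_reads(self) -> int:
        return self.total_reads - self.unedited_reads

    @property
    def in_window_indel_reads(self) -> int:
        return int(self.deletions.sum() + self.insertions.sum())


@dataclass
class DemuxResult:
    windows: dict[str, list[str]]
    counters: Counter = field(default_factory=Counter)


def demux_and_extract(reads, libraries: dict[str, LibraryDef]) -> DemuxResult:
    """Assign reads to libraries and extract surrogate windows.

    A read is assigned to the unique library whose ``spacer + scaffold``
    occurs as a substring, and kept only if the linker signature follows;
    the window is the subsequence between scaffold end and linker start
    (no length restriction).  Reads matching several libraries are
    dropped and counted — that signals a library design collision.
    """
    keys = {gid: (lib.spacer + lib.scaffold).upper() for gid, lib in libraries.items()}
    if len(set(keys.values())) != len(keys):
        raise ValueError("library spacer+scaffold keys are not unique")
    out = DemuxResult({gid: [] for gid in libraries})
    for read in reads:
        read = read.upper()
        matches = [(gid, read.find(key)) for gid, key in keys.items() if key in read]
        if not matches:
            out.counters["unassigned"] += 1
            continue
        if len(matches) > 1:
            out.counters["ambiguous"] += 1
            logger.warning("read matches %d libraries; possible design collision", len(matches))
            continue
        gid, pos = matches[0]
        tail = read[pos + len(keys[gid]):]
        # the linker signature marks the END of the surrogate window; use
        # the last occurrence so windows that contain it by chance parse
        link = tail.rfind(LINKER_SIGNATURE)
        if link < 0:
            out.counters["no_linker"] += 1
            continue
        out.windows[gid].append(tail[:link])
        out.counters["assigned"] += 1
    return out


def subtract_background(sample_windows: dict[str, list[str]],
                        control_windows: dict[str, list[str]],
                        references: dict[str, str]) -> dict[str, list[str]]:
    """Remove sample windows whose variant sequence also occurs in the control.

    The 37-bp reference itself is never subtracted — unedited reads
    legitimately dominate the control; only non-reference sequences seen
    in the unedited control (synthesis/PCR/sequencing artifacts) are
    treated as background.
    """
    cleaned = {}
    for gid, windows in sample_windows.items():
        if gid not in control_windows:
            logger.warning("library %s absent from control; no background subtraction", gid)
            cleaned[gid] = list(windows)
            continue
        ref = references[gid].upper()
        background = {w.upper() for w in control_windows[gid]} - {ref}
        cleaned[gid] = [w for w in windows if w.upper() not in background]
    return cleaned


def profile_from_lengths(lengths: np.ndarray) -> IndelProfile:
    """Build an :class:`IndelProfile` from an array of window lengths."""
    lengths = np.asarray(lengths, dtype=np.int64)
    total = int(lengths.size)
    unedited = int(np.count_nonzero(lengths == REF_LEN))
    dels = np.zeros(MAX_DEL, dtype=np.int64)
    ins = np.zeros(MAX_INS, dtype=np.int64)
    in_win = lengths[(lengths >= MIN_WINDOW) & (lengths <= MAX_WINDOW) & (lengths != REF_LEN)]
    for ln, cnt in zip(*np.unique(in_win, return_counts=True)):
        if ln < REF_LEN:
            dels[REF_LEN - ln - 1] = cnt
        else:
            ins[ln - REF_LEN - 1] = cnt
    out = total - unedited - int(dels.sum()) - int(ins.sum())
    return IndelProfile(total, unedited, dels, ins, out)


def profile_and_efficiency(windows, min_reads: int = DEFAULT_MIN_READS):
    """Eq-style per-library quantification.

    Returns ``(IndelProfile, record)`` where ``record`` is a dict with
    the total editing efficiency in percent (reads of length != 37 over
    all reads), the read support, and an ``excluded`` flag set when the
    library has fewer than ``min_reads`` reads.
    """
    if hasattr(windows, "dtype"):
        lengths = np.asarray(windows, dtype=np.int64)
    else:
        windows = list(windows)
        lengths = np.fromiter((len(w) for w in windows), dtype=np.int64, count=len(windows))
    if lengths.size == 0:
        raise ValueError("cannot compute efficiency of an empty window list")
    prof = profile_from_lengths(lengths)
    efficiency = 100.0 * prof.edited_reads / prof.total_reads
    record = {
        "total_reads": prof.total_reads,
        "unedited_reads": prof.unedited_reads,
        "efficiency": efficiency,
        "excluded": prof.total_reads < min_reads,
    }
    return prof, record


def quantify_pool(windows_by_guide: dict[str, list[str]],
                  min_reads: int = DEFAULT_MIN_READS) -> tuple[pd.DataFrame, dict[str, IndelProfile]]:
    """Per-guide efficiency table plus profiles for a whole pool."""
    rows = []
    profiles = {}
    for gid, windows in windows_by_guide.items():
        if not len(windows):
            continue
        prof, rec = profile_and_efficiency(windows, min_reads=min_reads)
        profiles[gid] = prof
        rows.append({"guide_id": gid, **rec})
    return pd.DataFrame(rows), profiles


def pool_indel_fraction(profiles) -> float:
    """Pool-level average indel fraction (percent): in-window indel reads
    over the total reads of the whole library pool."""
    profiles = list(profiles.values()) if isinstance(profiles, dict) else list(profiles)
    total = sum(p.total_reads for p in profiles)
    if total == 0:
        raise ValueError("empty pool")
    indel = sum(p.in_window_indel_reads for p in profiles)
    return 100.0 * indel / total


def insertion_base_spectrum(windows, site) -> pd.DataFrame:
    """4x4 count table of 1-bp insertions at the blunt cut site.

    Rows: identity of protospacer position N17 (constant per site);
    columns: inserted base.  Only windows of length 38 that align to the
    reference with a single 1-bp insertion placeable at the cut (between
    protospacer positions 17 and 18, i.e. 3 bp upstream of the PAM) are
    counted; the insertion is left-aligned.  Everything else counts as
    ambiguous and is excluded.
    """
    ref = site.seq37.upper()
    cut = 10 + 17  # up10 + 17 protospacer bases, 0-based index of the cut
    n17 = ref[10 + 16]
    table = pd.DataFrame(0, index=list("ACGT"), columns=list("ACGT"))
    ambiguous = 0
    for w in windows:
        w = w.upper()
        if len(w) != REF_LEN + 1:
            raise ValueError(f"insertion spectrum expects 38-bp windows, got {len(w)}")
        lcp = 0
        while lcp < REF_LEN and w[lcp] == ref[lcp]:
            lcp += 1
        lcs = 0
        while lcs < REF_LEN and w[-1 - lcs] == ref[-1 - lcs]:
            lcs += 1
        lo, hi = REF_LEN - lcs, min(lcp, REF_LEN)  # feasible insertion positions
        if lo > hi or not (lo <= cut <= hi):
            ambiguous += 1
            continue
        table.loc[n17, w[cut]] += 1
    table.attrs["ambiguous"] = ambiguous
    return table


def merge_days(day_a: pd.DataFrame, day_b: pd.DataFrame,
               key: str = "guide_id", value: str = "efficiency") -> tuple[pd.DataFrame, float]:
    """Intersect two measurement days and average their efficiencies.

    Returns the merged frame and the Pearson correlation between the
    paired per-day values.
    """
    merged = day_a[[key, value]].merge(day_b[[key, value]], on=key, suffixes=("_a", "_b"))
    if merged.empty:
        raise ValueError("no overlapping guides between the two days")
    r = float(stats.pearsonr(merged[f"{value}_a"], merged[f"{value}_b"])[0]) if len(merged) > 1 else float("nan")
    merged[value] = (merged[f"{value}_a"] + merged[f"{value}_b"]) / 2.0
    return merged[[key, value, f"{value}_a", f"{value}_b"]], r
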