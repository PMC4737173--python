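"""Raw read processing: adapter trimming, channel demultiplexing, targeted
alignment and RT-stop inference, and ligation-dimer QC.

The experimental geometry this module assumes (and the simulator in
:mod:`shapeseq.simulate` emulates):

* read 1 begins with a channel handle barcode, followed by target-derived
  sequence in *sense* orientation starting at the 5'-most position the
  cDNA covers, followed by adapter read-through when the fragment is
  shorter than the read;
* read 2 carries the opposite end (adapter side) and is not needed to
  infer the stop, so single-end collections are accepted everywhere.

Because a targeted run probes a handful of short, known RNAs, alignment
is done by direct placement of the read on each target (exact substring
fast path, Hamming scan fallback) rather than by a general-purpose
short-read aligner.  This keeps the stop-coordinate convention — the
modification site is one nucleotide 5' of the first covered position —
explicit and auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio.Data.IUPACData import ambiguous_dna_values

from .counts import FULL_LENGTH, CHANNELS, PLUS, MINUS, FragmentCounts, StopObservation, tabulate_stops
from .targets import RunConfig, TargetRNA, as_dna


@dataclass
class ReadPair:
    """A (possibly single-end) sequencing read pair."""

    read1: str
    read2: str = ""
    qual1: str = ""
    qual2: str = ""
    channel: str | None = None  # set by demux: "plus" | "minus" | None
    is_dimer: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        if not self.read1:
            raise ValueError("read1 must be non-empty")


# ---------------------------------------------------------------------------
# adapter trimming


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def trim_adapter(read: str, adapter: str, min_overlap: int = 5) -> str:
    """Remove the longest read suffix that matches a prefix of the adapter.

    A suffix of length L matches when it differs from adapter[:L] in at
    most L // 10 positions (one mismatch allowed per 10 nt of overlap).
    Overlaps shorter than ``min_overlap`` are never trimmed; a read with
    no match is returned unchanged.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    max_len = min(len(read), len(adapter))
    for L in range(max_len, min_overlap - 1, -1):
        if _hamming(read[-L:], adapter[:L]) <= L // 10:
            return read[:-L]
    return read


# ---------------------------------------------------------------------------
# channel demultiplexing

def _iupac_match(base: str, code: str) -> bool:
    return base in ambiguous_dna_values.get(code, code)


def matches_pattern(sequence: str, pattern: str) -> bool:
    """Do the leading bases of ``sequence`` match an IUPAC pattern?"""
    if len(sequence) < len(pattern):
        return False
    return all(_iupac_match(b, c) for b, c in zip(sequence, pattern))


def demux_by_handle(pair: ReadPair, plus_handle: str, minus_handle: str) -> ReadPair:
    """Assign the channel from read 1's leading handle bases and strip them.

    First-match precedence is *not* used: a read matching both patterns is
    ambiguous and stays unassigned (callers tally this in QC).
    """
    if len(plus_handle) != len(minus_handle):
        raise ValueError("handle patterns must have equal length")
    hit_plus = matches_pattern(pair.read1, plus_handle)
    hit_minus = matches_pattern(pair.read1, minus_handle)
    if hit_plus == hit_minus:  # neither, or ambiguous
        return replace(pair, channel=None)
    channel = PLUS if hit_plus else MINUS
    h = len(plus_handle)
    return replace(
        pair,
        read1=pair.read1[h:],
        qual1=pair.qual1[h:] if pair.qual1 else "",
        channel=channel,
    )


def is_ambiguous_handle(pair: ReadPair, plus_handle: str, minus_handle: str) -> bool:
    return matches_pattern(pair.read1, plus_handle) and matches_pattern(pair.read1, minus_handle)


# ---------------------------------------------------------------------------
# targeted alignment


def _placements(read: str, target_dna: str, max_mismatches: int) -> list[tuple[int, int]]:
    """All (offset, mismatches) placements of ``read`` fully inside
    ``target_dna`` with at most ``max_mismatches`` differences."""
    hits = []
    # exact fast path
    start = target_dna.find(read)
    while start != -1:
        hits.append((start, 0))
        start = target_dna.find(read, start + 1)
    if max_mismatches > 0:
        exact = {off for off, _ in hits}
        for off in range(len(target_dna) - len(read) + 1):
            if off in exact:
                continue
            mm = 0
            for a, b in zip(read, target_dna[off:]):
                if a != b:
                    mm += 1
                    if mm > max_mismatches:
                        break
            else:
                hits.append((off, mm))
    return hits


def align_and_infer_stop(
    pair: ReadPair,
    targets: Sequence[TargetRNA],
    max_mismatches: int = 1,
    max_end_clip: int = 4,
) -> StopObservation | None:
    """Place a trimmed, demuxed read on its target and infer the RT stop.

    The read (sense orientation) must fit at a unique position across the
    whole panel; with p the 1-based target position of the 5'-most covered
    base, the modification site is p - 1 ("halt one nucleotide before the
    modification"), and coverage of position 1 is a full-length extension.
    Multi-mapping reads, reads exceeding ``max_mismatches`` everywhere and
    empty reads yield no hit (``None``).

    Adapter trimming cannot remove read-through remnants shorter than its
    minimum overlap, so when the full read has no placement up to
    ``max_end_clip`` trailing bases are clipped and placement retried;
    the 3' end never informs the stop coordinate.
    """
    if pair.channel not in CHANNELS:
        raise ValueError("read must be demultiplexed before alignment")
    panel = [(t.name, as_dna(t.sequence)) for t in targets]
    for clip in range(0, max_end_clip + 1):
        read = pair.read1[: len(pair.read1) - clip]
        if not read:
            return None
        best: tuple[int, str, int] | None = None  # (mismatches, target, offset)
        n_best = 0
        for name, tdna in panel:
            for off, mm in _placements(read, tdna, max_mismatches):
                if best is None or mm < best[0]:
                    best = (mm, name, off)
                    n_best = 1
                elif mm == best[0]:
                    n_best += 1
        if best is None:
            continue
        if n_best > 1:
            return None
        _, name, off = best
        p = off + 1
        stop = FULL_LENGTH if p == 1 else p - 1
        return StopObservation(target=name, stop_site=stop, channel=pair.channel)
    return None


# ---------------------------------------------------------------------------
# ligation-dimer QC


def _matches_with_mismatches(a: str, b: str, allowed: int) -> bool:
    return len(a) == len(b) and _hamming(a, b) <= allowed


def is_ligation_dimer(
    read1: str,
    rt_primer_sites: Sequence[str],
    adapter: str,
    handle_length: int = 0,
    max_mismatches: int = 1,
) -> bool:
    """Is read 1 an RT-primer/adapter ligation dimer?

    A dimer has no target-derived insert: after skipping the handle, the
    read consists of an RT-primer-site sequence directly joined to the
    adapter.  Each segment tolerates at most ``max_mismatches``
    differences; the adapter may be truncated by the read end.
    """
    body = read1[handle_length:]
    for site in rt_primer_sites:
        site = as_dna(site)
        if len(body) < len(site):
            continue
        if _hamming(body[: len(site)], site) > max_mismatches:
            continue
        rest = body[len(site):]
        if _matches_with_mismatches(rest, adapter[: len(rest)], max_mismatches):
            return True
    return False


def ligation_dimer_fraction(
    pairs: Iterable[ReadPair],
    rt_primer_sites: Sequence[str],
    adapter: str,
    handle_length: int = 0,
    max_mismatches: int = 1,
) -> float:
    """Fraction of reads that are RT-primer/adapter ligation dimers."""
    total = 0
    dimers = 0
    for pair in pairs:
        total += 1
        dimers += is_ligation_dimer(
            pair.read1, rt_primer_sites, adapter, handle_length, max_mismatches
        )
    if total == 0:
        raise ValueError("dimer fraction is undefined on an empty read collection")
    return dimers / total


# ---------------------------------------------------------------------------
# FASTQ input and the full read-to-counts pipeline


def read_paired_fastq(path1: str | Path, path2: str | Path | None = None) -> Iterator[ReadPair]:
    """Stream read pairs from FASTQ files (gzip accepted); single-end when
    ``path2`` is omitted."""
    import gzip

    from Bio import SeqIO

    def _open(p):
        p = str(p)
        return gzip.open(p, "rt") if p.endswith(".gz") else open(p)

    with _open(path1) as fh1:
        it1 = SeqIO.parse(fh1, "fastq")
        if path2 is None:
            for rec in it1:
                yield ReadPair(read1=str(rec.seq), name=rec.id)
        else:
            with _open(path2) as fh2:
                for r1, r2 in zip(it1, SeqIO.parse(fh2, "fastq")):
                    yield ReadPair(read1=str(r1.seq), read2=str(r2.seq), name=r1.id)


def process_read_pairs(
    pairs: Iterable[ReadPair],
    config: RunConfig,
) -> tuple[dict[str, dict[str, FragmentCounts]], dict]:
    """Run trim -> demux -> align -> tabulate over a read collection.

    Returns ``(counts, qc)`` where ``counts[target][channel]`` is a
    :class:`FragmentCounts` and ``qc`` summarises dimer, unassigned,
    ambiguous-handle and no-hit fractions plus per-target aligned totals.
    """
    handle_len = len(config.plus_handle)
    primer_sites = [t.rt_primer_site_sequence for t in config.targets]
    observations: dict[str, list[StopObservation]] = {t.name: [] for t in config.targets}
    probed_end = {t.name: t.probed_end for t in config.targets}

    total = dimers = unassigned = ambiguous = no_hit = aligned = primer_only = 0
    for pair in pairs:
        total += 1
        # dimers carry no handle: the barcode enters a read only through a
        # cDNA that copied target RNA, so the primer sits at offset 0
        if is_ligation_dimer(pair.read1, primer_sites, config.adapter, handle_length=0):
            dimers += 1
            continue
        trimmed = trim_adapter(pair.read1, config.adapter)
        if len(trimmed) <= handle_len:
            no_hit += 1
            continue
        work = replace(pair, read1=trimmed, qual1="")
        if is_ambiguous_handle(work, config.plus_handle, config.minus_handle):
            ambiguous += 1
            continue
        work = demux_by_handle(work, config.plus_handle, config.minus_handle)
        if work.channel is None:
            unassigned += 1
            continue
        obs = align_and_infer_stop(work, config.targets, config.max_mismatches)
        if obs is None:
            no_hit += 1
            continue
        if obs.stop_site is not FULL_LENGTH and obs.stop_site > probed_end[obs.target]:
            # stop within the gap/primer region, outside the probed window
            primer_only += 1
            continue
        observations[obs.target].append(obs)
        aligned += 1

    counts = {
        t.name: tabulate_stops(observations[t.name], t) for t in config.targets
    }
    qc = {
        "total_reads": total,
        "dimer_fraction": dimers / total if total else 0.0,
        "unassigned_fraction": (unassigned + ambiguous) / total if total else 0.0,
        "ambiguous_handle": ambiguous,
        "no_hit": no_hit,
        "outside_probed_region": primer_only,
        "aligned": aligned,
        "per_target_aligned": {
            name: sum(fc.total for fc in by_channel.values())
            for name, by_channel in counts.items()
        },
    }
    return counts, qc
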