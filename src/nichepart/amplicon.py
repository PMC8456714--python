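"""Paired-end amplicon read processing: demultiplex, trim, merge, assign.

The pipeline turns raw paired-end FASTQ reads of a short strain-discriminating
amplicon into per-sample strain counts:

1. :func:`demultiplex` — route read pairs to samples by their barcode.
2. :func:`trim_read` — quality trimming with Trimmomatic-style LEADING /
   TRAILING / SLIDINGWINDOW / MINLEN semantics.
3. :func:`merge_pair` — merge mates by the best ungapped overlap, taking the
   higher-quality base at disagreeing positions.
4. :func:`assign_strain` — read the bases at the panel's discriminatory SNP
   positions and match them against each strain's expected profile.

Coordinates are 0-based half-open throughout; qualities are Phred+33 only.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .panel import MarkerPanel

UNDETERMINED = "undetermined"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _qual_array(quals: str) -> np.ndarray:
    """Decode a Phred+33 quality string into integer scores."""
    return np.frombuffer(quals.encode("ascii"), dtype=np.uint8).astype(np.int32) - 33


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class ReadPair:
    """One paired-end read; qualities are Phred+33 strings."""

    read_id: str
    forward_seq: str
    forward_quals: str
    reverse_seq: str
    reverse_quals: str
    barcode: str | None = None

    def validate(self) -> None:
        for seq, quals, mate in (
            (self.forward_seq, self.forward_quals, "forward"),
            (self.reverse_seq, self.reverse_quals, "reverse"),
        ):
            if len(seq) != len(quals):
                raise ValueError(f"{mate} sequence/quality length mismatch in {self.read_id}")
            if len(quals) > 0:
                q = _qual_array(quals)
                if q.min() < 0 or q.max() > 60:
                    raise ValueError(f"{mate} qualities outside [0, 60] in {self.read_id}")


@dataclass(frozen=True)
class MergedRead:
    """Consensus of a merged mate pair."""

    read_id: str
    consensus_seq: str
    consensus_quals: str
    overlap_length: int


@dataclass(frozen=True)
class MergeFailure:
    """Unassembled pair with a reason code (no_overlap | length_out_of_range)."""

    read_id: str
    reason: str


@dataclass
class StrainCounts:
    """Per-sample assigned read counts.

    Invariant: ``sum(counts.values()) + ambiguous_count + unassigned_count ==
    total_merged``.
    """

    sample_id: str
    counts: dict[str, int]
    ambiguous_count: int = 0
    unassigned_count: int = 0
    total_merged: int = 0
    n_input_pairs: int = 0
    n_trimmed_pairs: int = 0

    def validate(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("negative strain count")
        total = sum(self.counts.values()) + self.ambiguous_count + self.unassigned_count
        if total != self.total_merged:
            raise ValueError(
                f"count conservation violated in {self.sample_id}: "
                f"{total} != {self.total_merged}"
            )

    @property
    def assigned_depth(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class Assignment:
    """Outcome of SNP-profile assignment: strain | ambiguous | unassigned."""

    kind: str  # "strain" | "ambiguous" | "unassigned"
    strain: str | None = None
    reason: str | None = None  # "length" | "profile" for unassigned


# ---------------------------------------------------------------------------
# demultiplexing


def read_barcode_map(path: str | Path) -> dict[str, str]:
    """Load a 2-column TSV (barcode, sample_id) into a barcode map."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            barcode, sample = line.split("\t")[:2]
            if barcode in ("barcode",):
                continue
            if barcode in mapping:
                raise ValueError(f"duplicate barcode {barcode!r}")
            mapping[barcode.upper()] = sample
    return mapping


def _validate_barcode_map(barcode_map: dict[str, str]) -> int:
    if not barcode_map:
        raise ValueError("empty barcode map")
    lengths = {len(b) for b in barcode_map}
    if len(lengths) != 1:
        raise ValueError(f"barcodes have unequal lengths: {sorted(lengths)}")
    return lengths.pop()


def demultiplex(
    reads: Iterable[ReadPair],
    barcode_map: dict[str, str],
    max_mismatch: int = 0,
) -> tuple[dict[str, list[ReadPair]], list[ReadPair]]:
    """Partition read pairs by barcode.

    Each read lands in exactly one sample bin or in the undetermined list;
    with ``max_mismatch > 0`` a read is assigned to the unique barcode within
    that Hamming distance, and reads tied between barcodes stay undetermined.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    bc_len = _validate_barcode_map(barcode_map)
    by_sample: dict[str, list[ReadPair]] = {s: [] for s in barcode_map.values()}
    undetermined: list[ReadPair] = []
    for pair in reads:
        bc = (pair.barcode or "").upper()
        if len(bc) != bc_len:
            if bc == "":
                undetermined.append(pair)
                continue
            raise ValueError(
                f"barcode length {len(bc)} in read {pair.read_id} != map length {bc_len}"
            )
        sample = barcode_map.get(bc)
        if sample is None and max_mismatch > 0:
            best: list[str] = []
            best_d = max_mismatch + 1
            for known, samp in barcode_map.items():
                d = sum(a != b for a, b in zip(bc, known))
                if d < best_d:
                    best, best_d = [samp], d
                elif d == best_d:
                    best.append(samp)
            if len(best) == 1 and best_d <= max_mismatch:
                sample = best[0]
        if sample is None:
            undetermined.append(pair)
        else:
            by_sample[sample].append(pair)
    return by_sample, undetermined


# ---------------------------------------------------------------------------
# quality trimming


def trim_read(
    seq: str,
    quals: str,
    leading_q: int = 28,
    trailing_q: int = 29,
    window: int = 4,
    window_q: float = 15.0,
    minlen: int = 90,
) -> tuple[str, str] | None:
    """Quality-trim one read; ``None`` means the read is discarded.

    Semantics follow Trimmomatic's LEADING / TRAILING / SLIDINGWINDOW /
    MINLEN steps in that order: strip leading bases with quality below
    ``leading_q`` and trailing bases below ``trailing_q``, then scan 5'→3'
    with windows of ``window`` bases and cut the read at the start of the
    first window whose mean quality falls below ``window_q``.  Any trailing
    bases below ``trailing_q`` exposed by the cut are removed as well, which
    makes the operation idempotent.  Reads shorter than ``minlen`` after
    trimming are discarded.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if len(seq) != len(quals):
        raise ValueError("sequence/quality length mismatch")
    if not seq:
        return None
    q = _qual_array(quals)
    start = 0
    n = len(q)
    while start < n and q[start] < leading_q:
        start += 1
    end = n
    while end > start and q[end - 1] < trailing_q:
        end -= 1
    if end - start >= window:
        kept = q[start:end].astype(np.float64)
        means = np.convolve(kept, np.ones(window), mode="valid") / window
        bad = np.flatnonzero(means < window_q)
        if bad.size:
            end = start + int(bad[0])
            while end > start and q[end - 1] < trailing_q:
                end -= 1
    if end - start < minlen:
        return None
    return seq[start:end], quals[start:end]


def trim_pair(pair: ReadPair, **kwargs) -> ReadPair | None:
    """Trim both mates; the pair is discarded if either mate fails."""
    fwd = trim_read(pair.forward_seq, pair.forward_quals, **kwargs)
    rev = trim_read(pair.reverse_seq, pair.reverse_quals, **kwargs)
    if fwd is None or rev is None:
        return None
    return ReadPair(pair.read_id, fwd[0], fwd[1], rev[0], rev[1], pair.barcode)


# ---------------------------------------------------------------------------
# pair merging


def merge_pair(
    pair: ReadPair,
    min_overlap: int = 10,
    min_assembly: int = 284,
    max_assembly: int = 290,
    min_consensus_q: int = 26,
    min_identity: float = 0.8,
) -> MergedRead | MergeFailure:
    """Merge a mate pair by its best ungapped overlap.

    The reverse mate is reverse-complemented and slid along the forward mate
    (the forward mate is taken as the 5' end of the fragment).  The offset
    maximising the number of matching bases wins; ties break toward the
    longer overlap, then the 5'-most offset.  At disagreeing overlap
    positions the base with the higher Phred score is kept and the consensus
    quality is the winning score; at agreeing positions the consensus quality
    is the higher of the two.  Consensus positions with quality below
    ``min_consensus_q`` are masked to ``N``.

    Returns :class:`MergeFailure` with reason ``no_overlap`` when no
    candidate overlap of at least ``min_overlap`` bases reaches
    ``min_identity``, and ``length_out_of_range`` when the best assembly
    falls outside ``[min_assembly, max_assembly]``.
    """
    fseq, fq = pair.forward_seq, _qual_array(pair.forward_quals)
    rseq = reverse_complement(pair.reverse_seq)
    rq = _qual_array(pair.reverse_quals)[::-1]
    f_arr = np.frombuffer(fseq.encode("ascii"), dtype=np.uint8)
    r_arr = np.frombuffer(rseq.encode("ascii"), dtype=np.uint8)
    m, n = len(f_arr), len(r_arr)
    if min(m, n) < min_overlap:
        return MergeFailure(pair.read_id, "no_overlap")

    best_offset = -1
    best_matches = -1
    best_ov = 0
    for offset in range(0, m - min_overlap + 1):
        ov = min(m - offset, n)
        matches = int(np.count_nonzero(f_arr[offset : offset + ov] == r_arr[:ov]))
        if matches > best_matches or (matches == best_matches and ov > best_ov):
            best_offset, best_matches, best_ov = offset, matches, ov
    if best_offset < 0 or best_matches / best_ov < min_identity:
        return MergeFailure(pair.read_id, "no_overlap")

    assembly_len = max(m, best_offset + n)
    if not (min_assembly <= assembly_len <= max_assembly):
        return MergeFailure(pair.read_id, "length_out_of_range")

    o = best_offset
    cons = np.empty(assembly_len, dtype=np.uint8)
    cq = np.zeros(assembly_len, dtype=np.int32)
    cons[:o] = f_arr[:o]
    cq[:o] = fq[:o]
    ov = best_ov
    f_ov, r_ov = f_arr[o : o + ov], r_arr[:ov]
    fq_ov, rq_ov = fq[o : o + ov], rq[:ov]
    agree = f_ov == r_ov
    take_fwd = agree | (fq_ov >= rq_ov)  # quality tie -> forward base
    cons[o : o + ov] = np.where(take_fwd, f_ov, r_ov)
    cq[o : o + ov] = np.where(
        agree, np.maximum(fq_ov, rq_ov), np.where(take_fwd, fq_ov, rq_ov)
    )
    if o + ov < assembly_len:
        if o + n > m:  # reverse mate extends past the forward mate
            cons[o + ov :] = r_arr[ov:]
            cq[o + ov :] = rq[ov:]
        else:  # forward mate extends past the reverse mate
            cons[o + ov :] = f_arr[o + ov :]
            cq[o + ov :] = fq[o + ov :]
    low = cq < min_consensus_q
    cons[low] = ord("N")
    seq_out = cons.tobytes().decode("ascii")
    quals_out = (np.clip(cq, 0, 60) + 33).astype(np.uint8).tobytes().decode("ascii")
    return MergedRead(pair.read_id, seq_out, quals_out, best_ov)


# ---------------------------------------------------------------------------
# strain assignment


def assign_strain(
    merged: MergedRead,
    panel: MarkerPanel,
    max_profile_mismatch: int = 0,
) -> Assignment:
    """Assign a merged read to a strain by its discriminatory-SNP profile.

    Reads whose consensus length differs from the panel's marker length are
    ``unassigned(length)``.  With the strict default, the bases at the SNP
    positions must equal exactly one strain's profile; ``unassigned(profile)``
    otherwise.  ``max_profile_mismatch > 0`` tolerates that many profile
    mismatches, with multiple equally good strains reported ``ambiguous``.
    """
    if len(merged.consensus_seq) != panel.marker_length:
        return Assignment("unassigned", reason="length")
    profile = panel.profile_of(merged.consensus_seq)
    if max_profile_mismatch == 0:
        hit = panel.match(profile)
        if hit is None:
            return Assignment("unassigned", reason="profile")
        return Assignment("strain", strain=hit)
    best_d = max_profile_mismatch + 1
    best: list[str] = []
    for name, expected in zip(panel.strain_names, panel.snp_profiles):
        d = sum(a != b for a, b in zip(profile, expected))
        if d < best_d:
            best, best_d = [name], d
        elif d == best_d:
            best.append(name)
    if best_d > max_profile_mismatch or not best:
        return Assignment("unassigned", reason="profile")
    if len(best) > 1:
        return Assignment("ambiguous")
    return Assignment("strain", strain=best[0])


# ---------------------------------------------------------------------------
# per-sample counting and relative abundance


def count_sample(
    sample_id: str,
    reads: Iterable[ReadPair],
    panel: MarkerPanel,
    trim_params: dict | None = None,
    merge_params: dict | None = None,
    max_profile_mismatch: int = 0,
) -> StrainCounts:
    """Run trim → merge → assign over one sample's read pairs."""
    trim_params = trim_params or {}
    merge_params = dict(merge_params or {})
    # default the assembly window to the marker itself
    merge_params.setdefault("min_assembly", panel.marker_length)
    merge_params.setdefault("max_assembly", panel.marker_length)
    counts = {name: 0 for name in panel.strain_names}
    ambiguous = unassigned = merged_n = n_input = n_trimmed = 0
    for pair in reads:
        n_input += 1
        trimmed = trim_pair(pair, **trim_params)
        if trimmed is None:
            continue
        n_trimmed += 1
        merged = merge_pair(trimmed, **merge_params)
        if isinstance(merged, MergeFailure):
            continue
        merged_n += 1
        result = assign_strain(merged, panel, max_profile_mismatch)
        if result.kind == "strain":
            counts[result.strain] += 1
        elif result.kind == "ambiguous":
            ambiguous += 1
        else:
            unassigned += 1
    out = StrainCounts(
        sample_id=sample_id,
        counts=counts,
        ambiguous_count=ambiguous,
        unassigned_count=unassigned,
        total_merged=merged_n,
        n_input_pairs=n_input,
        n_trimmed_pairs=n_trimmed,
    )
    out.validate()
    return out


def relative_abundance(counts: StrainCounts) -> dict[str, float]:
    """Strain proportions over assigned reads only (ambiguous/unassigned excluded)."""
    total = counts.assigned_depth
    if total <= 0:
        raise ValueError(f"sample {counts.sample_id} has no assigned reads")
    return {name: c / total for name, c in counts.counts.items()}


# ---------------------------------------------------------------------------
# FASTQ I/O

def _open_maybe_gzip(path: str | Path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _barcode_from_description(description: str) -> str | None:
    for token in description.split()[1:]:
        if token.startswith("bc="):
            return token[3:]
    return None


def read_fastq_pairs(r1_path: str | Path, r2_path: str | Path) -> Iterator[ReadPair]:
    """Stream mate pairs from two FASTQ files (optionally gzipped).

    Barcodes are read from a ``bc=SEQ`` token in the R1 description when
    present (the layout written by the read simulator).
    """
    with _open_maybe_gzip(r1_path) as fh1, _open_maybe_gzip(r2_path) as fh2:
        it1 = FastqGeneralIterator(fh1)
        it2 = FastqGeneralIterator(fh2)
        for (t1, s1, q1), (t2, s2, q2) in zip(it1, it2):
            id1, id2 = t1.split()[0], t2.split()[0]
            if id1 != id2:
                raise ValueError(f"mate id mismatch: {id1!r} vs {id2!r}")
            yield ReadPair(id1, s1.upper(), q1, s2.upper(), q2, _barcode_from_description(t1))


def write_fastq_pairs(
    pairs: Iterable[ReadPair], r1_path: str | Path, r2_path: str | Path
) -> None:
    """Write mate pairs as 4-line FASTQ; the barcode goes into a ``bc=`` token."""
    with open(r1_path, "w") as fh1, open(r2_path, "w") as fh2:
        for p in pairs:
            desc = f" bc={p.barcode}" if p.barcode else ""
            fh1.write(f"@{p.read_id}{desc}\n{p.forward_seq}\n+\n{p.forward_quals}\n")
            fh2.write(f"@{p.read_id}{desc}\n{p.reverse_seq}\n+\n{p.reverse_quals}\n")


def run_amplicon_pipeline(
    r1_path: str | Path,
    r2_path: str | Path,
    barcode_map: dict[str, str],
    panel: MarkerPanel,
    max_mismatch: int = 0,
    trim_params: dict | None = None,
    merge_params: dict | None = None,
    max_profile_mismatch: int = 0,
) -> dict[str, StrainCounts]:
    """Demultiplex two FASTQ files and count strains per sample."""
    by_sample, _ = demultiplex(
        read_fastq_pairs(r1_path, r2_path), barcode_map, max_mismatch
    )
    return {
        sample: count_sample(
            sample, reads, panel, trim_params, merge_params, max_profile_mismatch
        )
        for sample, reads in by_sample.items()
    }
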