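"""Triplex target-site discovery and third-strand (TFO) design.

A triplex target site (TTS) is a duplex-DNA tract, polypurine on one
strand, that can accommodate a third RNA strand in its major groove via
Hoogsteen base pairing.  This module scans annotated sigma-70 promoters
for such tracts, classifies their placement relative to the -35/-10
consensus boxes, designs purine- and pyrimidine-motif triplex-forming
oligonucleotides (TFOs), and assembles synthetic transcription-unit (TU)
layouts that place a TTS either within or downstream of the consensus.

Coordinate convention: 0-based, half-open intervals on the sense strand.
Template-strand candidates are reported in sense-strand coordinates with
``purine_strand="template"`` and ``purine_sequence`` read 5'->3' on the
template strand (i.e. the reverse complement of the sense interval).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
DNA_ALPHABET = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Sigma-70 consensus hexamer length (both boxes).
HEXAMER_LEN = 6


class SequenceInputError(ValueError):
    """Raised for malformed promoter records or scan inputs."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PromoterRecord:
    """An annotated bacterial promoter on the sense strand.

    ``minus35_start`` and ``minus10_start`` index the first base of each
    consensus hexamer; ``plus1_index`` is the transcription start site.
    """

    id: str
    sequence: str
    minus35_start: int
    minus10_start: int
    plus1_index: int
    source_locus: str | None = None

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq or set(seq) - DNA_ALPHABET:
            raise SequenceInputError(
                f"promoter {self.id!r}: sequence empty or outside A/C/G/T"
            )
        if not (0 <= self.minus35_start < self.minus10_start < self.plus1_index < len(seq)):
            raise SequenceInputError(
                f"promoter {self.id!r}: require 0 <= minus35 < minus10 < +1 < len"
            )


@dataclass(frozen=True)
class TTSCandidate:
    """A candidate triplex target site in sense-strand coordinates."""

    promoter_id: str
    start: int
    end: int
    purine_strand: str          # "sense" | "template"
    purine_fraction: float
    placement: str              # from classify_placement
    purine_sequence: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TFODesign:
    """A third-strand RNA designed against a TTS purine strand.

    Pyrimidine-motif TFOs (U/C alphabet) bind parallel to the purine
    strand; purine-motif TFOs (A/G) bind antiparallel.
    """

    tts_ref: str
    motif: str                  # "purine" | "pyrimidine"
    rna_sequence: str
    orientation: str            # "parallel" | "antiparallel"
    mismatch_positions: tuple[int, ...] = ()
    low_complexity: bool = False

    def __post_init__(self) -> None:
        allowed = {"pyrimidine": set("UC"), "purine": set("AG")}[self.motif]
        if set(self.rna_sequence) - allowed:
            raise SequenceInputError(
                f"{self.motif}-motif TFO alphabet must be {sorted(allowed)}"
            )
        expected = "parallel" if self.motif == "pyrimidine" else "antiparallel"
        if self.orientation != expected:
            raise SequenceInputError(
                f"{self.motif} motif requires {expected} orientation"
            )


@dataclass(frozen=True)
class TUScaffold:
    """A transcription-unit scaffold with placeholder slots.

    ``tts1_slot`` overlaps the promoter consensus, ``tts2_slot`` lies
    downstream of the -10 box; ``reporter_slot`` marks the reporter
    coding placeholder.  Slots are half-open intervals on the sense
    strand of ``sequence``.
    """

    sequence: str
    tts1_slot: tuple[int, int]
    tts2_slot: tuple[int, int]
    reporter_slot: tuple[int, int]
    minus35_start: int
    minus10_start: int


@dataclass(frozen=True)
class TUDesign:
    """One of the four tested TU geometries (A-D).

    A: TTS downstream of the consensus, purine strand on the template.
    B: TTS downstream, purine strand on the sense strand.
    C: TTS within the consensus, purine strand on the template.
    D: TTS within the consensus, purine strand on the sense strand.
    """

    geometry: str               # "A" | "B" | "C" | "D"
    tts_domain: str             # "TTS1_within_consensus" | "TTS2_downstream"
    purine_strand_placement: str  # "sense" | "template"
    tfo_motif: str
    assembled_sequence: str = ""


#: geometry letter -> (domain, purine strand placement); bijective.
GEOMETRY_MAP = {
    "A": ("TTS2_downstream", "template"),
    "B": ("TTS2_downstream", "sense"),
    "C": ("TTS1_within_consensus", "template"),
    "D": ("TTS1_within_consensus", "sense"),
}
_GEOMETRY_INV = {v: k for k, v in GEOMETRY_MAP.items()}


@dataclass(frozen=True)
class ScanParams:
    """Thresholds for the TTS scan.

    ``min_length`` — minimum tract length in nt.
    ``max_pyrimidine_fraction`` — interruptions allowed in the purine
    strand as a fraction of tract length.
    ``max_consecutive_interruptions`` — longest run of non-purines.
    ``proximity_margin`` — nt added around [-35 box, +1] to define the
    promoter-proximal window a tract must overlap.
    """

    min_length: int = 15
    max_pyrimidine_fraction: float = 0.10
    max_consecutive_interruptions: int = 1
    proximity_margin: int = 20


# ---------------------------------------------------------------------------
# TTS scanning
# ---------------------------------------------------------------------------

def _valid_tracts(seq: str, params: ScanParams) -> list[tuple[int, int]]:
    """Maximal intervals of ``seq`` whose purine content passes the thresholds.

    An interval qualifies when length >= min_length, it starts and ends
    on a purine (an edge interruption is just a shorter tract), the
    non-purine fraction is <= max_pyrimidine_fraction, and no run of
    non-purines exceeds max_consecutive_interruptions.  Returned
    intervals are maximal: no qualifying interval contains another
    returned one.
    """
    n = len(seq)
    is_pur = [c in PURINES for c in seq]
    # prefix sums of pyrimidine counts
    pref = [0]
    for p in is_pur:
        pref.append(pref[-1] + (0 if p else 1))

    def ok(s: int, e: int) -> bool:
        length = e - s
        if length < params.min_length:
            return False
        if not (is_pur[s] and is_pur[e - 1]):
            return False
        n_pyr = pref[e] - pref[s]
        if n_pyr > params.max_pyrimidine_fraction * length:
            return False
        run = 0
        for i in range(s, e):
            run = 0 if is_pur[i] else run + 1
            if run > params.max_consecutive_interruptions:
                return False
        return True

    # For each start, the set of valid ends is not contiguous (the
    # fraction constraint relaxes with length), so collect all valid
    # intervals and reduce to maximal ones.  n is promoter-scale
    # (<= a few hundred nt); O(n^2) with the early run check is fine.
    intervals = []
    for s in range(n):
        for e in range(s + params.min_length, n + 1):
            if ok(s, e):
                intervals.append((s, e))
    maximal = [
        (s, e) for (s, e) in intervals
        if not any((s2 <= s and e <= e2) and (s2, e2) != (s, e) for s2, e2 in intervals)
    ]
    # merge chains of overlapping maximal tracts into their union when the
    # union still qualifies; otherwise keep the longest member
    maximal.sort()
    merged: list[tuple[int, int]] = []
    for s, e in maximal:
        if merged and s < merged[-1][1]:
            ms, me = merged[-1]
            u = (ms, max(me, e))
            merged[-1] = u if ok(*u) else max([(ms, me), (s, e)], key=lambda t: t[1] - t[0])
        else:
            merged.append((s, e))
    return merged


def scan_tts(promoter: PromoterRecord, params: ScanParams | None = None) -> list[TTSCandidate]:
    """Find TTS candidates on both strands near the promoter consensus.

    Scans the sense strand and its reverse complement for maximal
    polypurine tracts, keeps those overlapping the window
    ``[minus35_start - margin, plus1_index + margin]`` (clamped to the
    sequence), and reports them in sense-strand coordinates sorted by
    start.
    """
    params = params or ScanParams()
    seq = promoter.sequence
    n = len(seq)
    win_lo = max(0, promoter.minus35_start - params.proximity_margin)
    win_hi = min(n, promoter.plus1_index + params.proximity_margin)

    out: list[TTSCandidate] = []
    for strand, strand_seq in (("sense", seq), ("template", reverse_complement(seq))):
        for s, e in _valid_tracts(strand_seq, params):
            if strand == "template":
                s, e = n - e, n - s       # map back to sense coordinates
            if not (s < win_hi and e > win_lo):
                continue
            sense_interval = seq[s:e]
            purine_seq = sense_interval if strand == "sense" else reverse_complement(sense_interval)
            frac = sum(c in PURINES for c in purine_seq) / len(purine_seq)
            out.append(
                TTSCandidate(
                    promoter_id=promoter.id,
                    start=s,
                    end=e,
                    purine_strand=strand,
                    purine_fraction=frac,
                    placement=_classify(s, e, promoter),
                    purine_sequence=purine_seq,
                )
            )
    out.sort(key=lambda t: (t.start, t.purine_strand))
    return out


def _classify(start: int, end: int, promoter: PromoterRecord) -> str:
    box_lo = promoter.minus35_start
    box_hi = promoter.minus10_start + HEXAMER_LEN
    if box_lo <= start and end <= box_hi:
        return "within_consensus"
    if start >= box_hi:
        return "downstream"
    if end <= box_lo:
        return "upstream"
    return "spanning"


def classify_placement(tts: TTSCandidate, promoter: PromoterRecord) -> str:
    """Placement of a TTS interval relative to the -35/-10 consensus.

    ``within_consensus`` when contained in [-35 start, -10 end);
    ``downstream`` when it starts at or after the -10 box end;
    ``upstream`` when it ends at or before the -35 box start;
    ``spanning`` otherwise.
    """
    if not (0 <= tts.start < tts.end <= len(promoter.sequence)):
        raise SequenceInputError(
            f"TTS interval [{tts.start}, {tts.end}) outside promoter {promoter.id!r}"
        )
    return _classify(tts.start, tts.end, promoter)


# ---------------------------------------------------------------------------
# TFO design
# ---------------------------------------------------------------------------

# Hoogsteen third-strand partner for each purine-strand base.  For a
# pyrimidine interruption the partner of the complementary purine on the
# other strand is used and the position is recorded as a mismatch.
_PY_MAP = {"A": "U", "G": "C", "T": "U", "C": "C"}
_PU_MAP = {"A": "A", "G": "G", "T": "A", "C": "G"}

#: a purine tract whose dominant base exceeds this fraction is flagged
#: low-complexity (homopolymeric tracts form poor triplexes).
LOW_COMPLEXITY_DOMINANT_FRACTION = 0.8


def design_tfo(tts: TTSCandidate, motif: str) -> TFODesign:
    """Design a Hoogsteen third strand against the TTS purine strand.

    Pyrimidine motif: positionwise A->U, G->C over the purine strand
    read 5'->3'; binds parallel.  Purine motif: A->A, G->G then the
    string is reversed so the returned 5'->3' RNA runs antiparallel to
    the purine strand.  Pyrimidine interruptions get the Hoogsteen
    partner of the complementary purine; their indices (in the TFO's own
    5'->3' frame) are recorded in ``mismatch_positions``.
    """
    pur = tts.purine_sequence
    if not pur:
        raise SequenceInputError("empty purine_sequence")
    if motif not in ("purine", "pyrimidine"):
        raise SequenceInputError(f"unknown motif {motif!r}")
    table = _PY_MAP if motif == "pyrimidine" else _PU_MAP
    bases = [table[c] for c in pur]
    interruptions = [i for i, c in enumerate(pur) if c not in PURINES]
    if motif == "purine":
        bases.reverse()
        interruptions = [len(pur) - 1 - i for i in interruptions]
    counts = {c: pur.count(c) for c in set(pur)}
    low = max(counts.values()) / len(pur) >= LOW_COMPLEXITY_DOMINANT_FRACTION
    return TFODesign(
        tts_ref=tts.promoter_id,
        motif=motif,
        rna_sequence="".join(bases),
        orientation="parallel" if motif == "pyrimidine" else "antiparallel",
        mismatch_positions=tuple(sorted(interruptions)),
        low_complexity=low,
    )


_SWAP = {"U": "C", "C": "U", "A": "G", "G": "A"}


def mutate_tfo(tfo: TFODesign, position: int) -> TFODesign:
    """Introduce a single non-Hoogsteen substitution at ``position``.

    Swaps within the motif alphabet (U<->C, A<->G).  Mutating a
    position already in ``mismatch_positions`` reverts it; a design
    identical to a perfect one ends with an empty mismatch list.
    """
    if not (0 <= position < len(tfo.rna_sequence)):
        raise SequenceInputError(f"position {position} out of range")
    seq = list(tfo.rna_sequence)
    seq[position] = _SWAP[seq[position]]
    if position in tfo.mismatch_positions:
        mismatches = tuple(p for p in tfo.mismatch_positions if p != position)
    else:
        mismatches = tuple(sorted(tfo.mismatch_positions + (position,)))
    return replace(tfo, rna_sequence="".join(seq), mismatch_positions=mismatches)


def purine_strand_from_tfo(tfo: TFODesign) -> str:
    """Re-derive the DNA purine strand (5'->3') a TFO was designed against.

    Inverse of :func:`design_tfo` for perfect designs: U->A, C->G for
    the pyrimidine motif; reversal then identity for the purine motif.
    """
    if tfo.motif == "pyrimidine":
        return tfo.rna_sequence.translate(str.maketrans("UC", "AG"))
    return tfo.rna_sequence[::-1]


# ---------------------------------------------------------------------------
# TU enumeration and assembly
# ---------------------------------------------------------------------------

def enumerate_designs(
    tts_list: Sequence[TTSCandidate],
    domains: Sequence[str],
    placements: Sequence[str],
    motifs: Sequence[str],
) -> list[tuple[TUDesign, TFODesign]]:
    """Cartesian product of TTSs x domains x strand placements x motifs.

    One TTS under the full factor structure (2 domains x 2 placements x
    2 motifs) yields the 8 tested combinations; three triplex-forming
    TTSs yield 24.
    """
    if not (tts_list and domains and placements and motifs):
        raise SequenceInputError("all factor lists must be non-empty")
    out = []
    for tts, domain, placement, motif in itertools.product(tts_list, domains, placements, motifs):
        geometry = _GEOMETRY_INV[(domain, placement)]
        tu = TUDesign(
            geometry=geometry,
            tts_domain=domain,
            purine_strand_placement=placement,
            tfo_motif=motif,
        )
        out.append((tu, design_tfo(tts, motif)))
    return out


def build_tu(tts: TTSCandidate, geometry: str, scaffold: TUScaffold) -> TUDesign:
    """Substitute a TTS into a TU scaffold slot for the given geometry.

    Sense placement inserts ``purine_sequence`` verbatim; template
    placement inserts its reverse complement.  For geometries A/B
    (downstream slot) the -35/-10 hexamers must be untouched.
    """
    domain, placement = GEOMETRY_MAP[geometry]
    slot = scaffold.tts2_slot if domain == "TTS2_downstream" else scaffold.tts1_slot
    slot_len = slot[1] - slot[0]
    if slot_len != tts.length:
        raise SequenceInputError(
            f"placeholder length mismatch: slot expects {slot_len} nt, TTS is {tts.length} nt"
        )
    insert = tts.purine_sequence if placement == "sense" else reverse_complement(tts.purine_sequence)
    seq = scaffold.sequence[: slot[0]] + insert + scaffold.sequence[slot[1]:]
    if geometry in ("A", "B"):
        for box_start in (scaffold.minus35_start, scaffold.minus10_start):
            if (seq[box_start : box_start + HEXAMER_LEN]
                    != scaffold.sequence[box_start : box_start + HEXAMER_LEN]):
                raise SequenceInputError(
                    f"geometry {geometry} must not alter the consensus hexamers"
                )
    return TUDesign(
        geometry=geometry,
        tts_domain=domain,
        purine_strand_placement=placement,
        tfo_motif="",
        assembled_sequence=seq,
    )


# ---------------------------------------------------------------------------
# I/O: FASTA promoters + TSV annotations; TSV/FASTA outputs
# ---------------------------------------------------------------------------

def read_promoters(fasta_path: str | Path, sidecar_tsv: str | Path) -> list[PromoterRecord]:
    """Read promoters from FASTA plus a TSV sidecar of element coordinates.

    The sidecar has columns: id, minus35_start, minus10_start, plus1_index.
    """
    from Bio import SeqIO

    annot: dict[str, tuple[int, int, int]] = {}
    with open(sidecar_tsv) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts or not parts[0]:
                continue
            annot[parts[idx["id"]]] = (
                int(parts[idx["minus35_start"]]),
                int(parts[idx["minus10_start"]]),
                int(parts[idx["plus1_index"]]),
            )
    records = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in annot:
            raise SequenceInputError(f"no sidecar annotation for {rec.id!r}")
        m35, m10, p1 = annot[rec.id]
        records.append(
            PromoterRecord(
                id=rec.id, sequence=str(rec.seq), minus35_start=m35,
                minus10_start=m10, plus1_index=p1,
            )
        )
    return records


def write_tts_tsv(candidates: Iterable[TTSCandidate], path: str | Path) -> None:
    """Write candidates as a BED-like TSV."""
    with open(path, "w") as fh:
        fh.write("promoter_id\tstart\tend\tpurine_strand\tpurine_fraction\tplacement\tpurine_sequence\n")
        for c in candidates:
            fh.write(
                f"{c.promoter_id}\t{c.start}\t{c.end}\t{c.purine_strand}\t"
                f"{c.purine_fraction:.4f}\t{c.placement}\t{c.purine_sequence}\n"
            )


def write_tfo_fasta(designs: Iterable[TFODesign], path: str | Path) -> None:
    """Write TFO designs as RNA FASTA with motif=/orientation= header tags."""
    with open(path, "w") as fh:
        for i, d in enumerate(designs):
            fh.write(
                f">{d.tts_ref}_tfo{i} motif={d.motif} orientation={d.orientation}\n"
                f"{d.rna_sequence}\n"
            )
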