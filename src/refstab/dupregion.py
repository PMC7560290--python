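"""Duplicated-gene (homeolog) sequence handling for primer placement.

Polyploid genomes carry near-identical gene copies whose individual
expression can diverge; qPCR primers placed in regions *identical* across
all copies measure the aggregate transcript pool instead of one copy.
This module provides the sequence-level checks behind that design:

* global pairwise identity between copies,
* discovery of maximal windows exactly shared by every copy (candidate
  priming regions),
* exact-match in-silico PCR to predict amplicons and their lengths,
* verification of a primer pair against standard design constraints
  (length, Tm, GC content, product size).

Coordinates are 1-based inclusive on the sense strand; reverse primers are
given 5'->3' on the antisense strand and matched on the template as their
reverse complement.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import Align, SeqIO
from Bio.Seq import Seq
from Bio.SeqUtils import MeltingTemp, gc_fraction

__all__ = [
    "SequenceRecord",
    "PrimerPair",
    "PrimerReport",
    "Amplicon",
    "IdenticalWindow",
    "read_fasta",
    "read_primers",
    "pairwise_identity",
    "identical_windows",
    "in_silico_pcr",
    "check_primer_constraints",
    "synthetic_template",
]

_SEQ_ALPHABET = re.compile(r"^[ACGTN]+$")
_PRIMER_ALPHABET = re.compile(r"^[ACGT]+$")

#: Primer-design acceptance windows: length (bp), melting temperature (degC),
#: GC content (%), product size (bp).
PRIMER_LENGTH_RANGE = (20, 24)
PRIMER_TM_RANGE = (55.0, 65.0)
PRIMER_GC_RANGE = (45.0, 60.0)
PRODUCT_SIZE_RANGE = (80, 200)


@dataclass(frozen=True)
class SequenceRecord:
    """Uppercase nucleotide sequence over {A, C, G, T, N}."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")
        m = _SEQ_ALPHABET.match(self.seq)
        if not m:
            pos = next(
                i for i, c in enumerate(self.seq, start=1) if c not in "ACGTN"
            )
            raise ValueError(
                f"sequence {self.id!r}: invalid character "
                f"{self.seq[pos - 1]!r} at position {pos}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class PrimerPair:
    """Forward/reverse primer pair, both written 5'->3'.

    The forward primer matches the sense strand; the reverse primer matches
    the template as its reverse complement downstream of the forward site.
    """

    name: str
    forward: str
    reverse: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "forward", self.forward.upper())
        object.__setattr__(self, "reverse", self.reverse.upper())
        for label, p in (("forward", self.forward), ("reverse", self.reverse)):
            if len(p) < 10:
                raise ValueError(f"{self.name}: {label} primer shorter than 10 nt")
            if not _PRIMER_ALPHABET.match(p):
                raise ValueError(f"{self.name}: {label} primer has non-ACGT characters")

    @property
    def reverse_site(self) -> str:
        """Sense-strand sequence the reverse primer anneals opposite to."""
        return str(Seq(self.reverse).reverse_complement())


@dataclass
class PrimerReport:
    pair: PrimerPair
    length_ok: bool
    tm_ok: bool
    gc_ok: bool
    product_size_ok: bool
    gc_percent: dict[str, float]       # per primer: forward / reverse
    tm_celsius: dict[str, float]
    tm_method: str
    product_length: int | None


@dataclass(frozen=True)
class Amplicon:
    template_id: str
    start: int   # 1-based inclusive, sense strand
    end: int     # 1-based inclusive
    sequence: str
    forward_mismatches: int = 0
    reverse_mismatches: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class IdenticalWindow:
    start_per_sequence: dict[str, int]  # 1-based start in each input sequence
    length: int
    sequence: str


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    records = [
        SequenceRecord(id=r.id, seq=str(r.seq)) for r in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def read_primers(path: str | Path) -> list[PrimerPair]:
    """Read primer pairs from TSV with columns: name, forward, reverse."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"name", "forward", "reverse"}
    if not required.issubset(df.columns):
        raise ValueError(f"primer TSV needs columns {sorted(required)}")
    return [
        PrimerPair(name=r["name"], forward=r["forward"], reverse=r["reverse"])
        for _, r in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# Pairwise identity


def pairwise_identity(
    a: SequenceRecord,
    b: SequenceRecord,
    *,
    match: float = 1.0,
    mismatch: float = 0.0,
    gap: float = -1.0,
) -> float:
    """Percent identity from a global alignment.

    Scoring: match +1, mismatch 0, linear gap penalty (parameters are
    arguments so the metric is always recorded with its settings).
    Identity = identical columns / alignment length x 100, gaps counted in
    the length.
    """
    if gap >= 0:
        raise ValueError("gap penalty must be negative")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    aln = aligner.align(a.seq, b.seq)[0]
    counts = aln.counts()
    return counts.identities / aln.length * 100.0


# ---------------------------------------------------------------------------
# Identical-window discovery


def identical_windows(
    seqs: Sequence[SequenceRecord], min_len: int = 20
) -> list[IdenticalWindow]:
    """Maximal substrings of length >= min_len exactly shared by all inputs.

    "Identical region" means exact identity, not high-scoring alignment:
    every reported window occurs verbatim (no mismatches, no gaps) in every
    input sequence, and cannot be extended left or right without losing
    that property.  Windows are anchored on the first sequence and ordered
    by their position there; for the other sequences the first occurrence
    is reported.
    """
    if len(seqs) < 2:
        raise ValueError("identical-window search needs >=2 sequences")
    if min_len < 15:
        import warnings

        warnings.warn(
            f"min_len={min_len} is below a usable primer length", stacklevel=2
        )
    s0 = seqs[0].seq
    others = [s.seq for s in seqs[1:]]
    n = len(s0)

    # ext[i] = longest l with s0[i:i+l] present in every other sequence.
    # ext[i] >= ext[i-1] - 1 (a common substring minus its first character
    # is still common), so a two-pointer scan suffices.
    ext = [0] * n
    l = 0
    for i in range(n):
        l = max(l - 1, 0)
        while i + l < n and all(s0[i : i + l + 1] in o for o in others):
            l += 1
        ext[i] = l

    windows: list[IdenticalWindow] = []
    for i in range(n):
        if ext[i] < min_len:
            continue
        if i > 0 and ext[i - 1] >= ext[i] + 1:
            continue  # contained in the window starting one position left
        sub = s0[i : i + ext[i]]
        starts = {seqs[0].id: i + 1}
        for rec, o in zip(seqs[1:], others):
            starts[rec.id] = o.index(sub) + 1
        windows.append(
            IdenticalWindow(start_per_sequence=starts, length=ext[i], sequence=sub)
        )
    return windows


# ---------------------------------------------------------------------------
# In-silico PCR


def _match_positions(template: str, probe: str, max_mismatches: int) -> list[tuple[int, int]]:
    """0-based start positions (and mismatch counts) where probe matches."""
    lp = len(probe)
    if max_mismatches == 0:
        out = []
        start = template.find(probe)
        while start != -1:
            out.append((start, 0))
            start = template.find(probe, start + 1)
        return out
    t = np.frombuffer(template.encode(), dtype=np.uint8)
    p = np.frombuffer(probe.encode(), dtype=np.uint8)
    if len(t) < lp:
        return []
    view = np.lib.stride_tricks.sliding_window_view(t, lp)
    mism = (view != p).sum(axis=1)
    return [(int(i), int(mm)) for i, mm in enumerate(mism) if mm <= max_mismatches]


def in_silico_pcr(
    primers: PrimerPair,
    templates: Sequence[SequenceRecord] | SequenceRecord,
    max_mismatches: int = 0,
) -> list[Amplicon]:
    """Predict PCR products by exact (or mismatch-tolerant) primer matching.

    For each template, every pairing of a forward-primer site with a
    downstream reverse-complement site of the reverse primer yields an
    amplicon spanning both primer footprints.  All products are reported;
    templates with no binding simply contribute none.  Exact matching
    (``max_mismatches=0``) is the default: a couple of mismatches is what
    distinguishes near-identical gene copies, so tolerant matching is an
    explicit opt-in.
    """
    if isinstance(templates, SequenceRecord):
        templates = [templates]
    rc = primers.reverse_site
    out: list[Amplicon] = []
    for t in templates:
        fwd_sites = _match_positions(t.seq, primers.forward, max_mismatches)
        rev_sites = _match_positions(t.seq, rc, max_mismatches)
        for fi, fmm in fwd_sites:
            for ri, rmm in rev_sites:
                if ri < fi:
                    continue
                end = ri + len(rc)  # 0-based exclusive
                out.append(
                    Amplicon(
                        template_id=t.id,
                        start=fi + 1,
                        end=end,
                        sequence=t.seq[fi:end],
                        forward_mismatches=fmm,
                        reverse_mismatches=rmm,
                    )
                )
    return out


# ---------------------------------------------------------------------------
# Primer-constraint verification


def check_primer_constraints(
    primers: PrimerPair, product_len: int | None = None
) -> PrimerReport:
    """Verify a primer pair against the standard design windows.

    Flags length 20-24 bp, nearest-neighbor Tm 55-65 degC, GC 45-60 % and
    product size 80-200 bp.  Tm uses the SantaLucia 1998 nearest-neighbor
    parameter set as implemented in Biopython (``MeltingTemp.Tm_NN``
    defaults); the method name travels with the report since Tm values are
    convention-dependent.
    """
    gc = {
        "forward": gc_fraction(primers.forward) * 100.0,
        "reverse": gc_fraction(primers.reverse) * 100.0,
    }
    tm = {
        "forward": float(MeltingTemp.Tm_NN(primers.forward)),
        "reverse": float(MeltingTemp.Tm_NN(primers.reverse)),
    }
    lo_l, hi_l = PRIMER_LENGTH_RANGE
    lo_t, hi_t = PRIMER_TM_RANGE
    lo_g, hi_g = PRIMER_GC_RANGE
    lo_p, hi_p = PRODUCT_SIZE_RANGE
    length_ok = all(lo_l <= len(p) <= hi_l for p in (primers.forward, primers.reverse))
    tm_ok = all(lo_t <= v <= hi_t for v in tm.values())
    gc_ok = all(lo_g <= v <= hi_g for v in gc.values())
    product_ok = product_len is None or (lo_p <= product_len <= hi_p)
    return PrimerReport(
        pair=primers,
        length_ok=length_ok,
        tm_ok=tm_ok,
        gc_ok=gc_ok,
        product_size_ok=bool(product_ok),
        gc_percent=gc,
        tm_celsius=tm,
        tm_method="Tm_NN (SantaLucia 1998 nearest-neighbor, Biopython defaults)",
        product_length=product_len,
    )


# ---------------------------------------------------------------------------
# Synthetic templates


def synthetic_template(
    primers: PrimerPair,
    product_length: int,
    *,
    template_id: str | None = None,
    flank: tuple[int, int] = (30, 30),
    insert: str | None = None,
    rng: np.random.Generator | None = None,
) -> SequenceRecord:
    """Construct a synthetic template carrying one amplicon of a given length.

    Synthetic stand-in for a real transcript: the forward primer and the
    reverse-complement of the reverse primer are embedded ``product_length``
    apart, separated by ``insert`` (random nucleotides when omitted), with
    random flanks.  Useful for exercising :func:`in_silico_pcr` when the
    true transcript sequences are not distributed with the package.
    """
    rc = primers.reverse_site
    inner = product_length - len(primers.forward) - len(rc)
    if inner < 0:
        raise ValueError(
            f"product_length {product_length} shorter than the two primer "
            f"footprints ({len(primers.forward)} + {len(rc)})"
        )
    rng = np.random.default_rng(0) if rng is None else rng
    bases = np.array(list("ACGT"))

    def rand(npts: int) -> str:
        return "".join(rng.choice(bases, size=npts)) if npts else ""

    if insert is None:
        insert = rand(inner)
    elif len(insert) != inner:
        raise ValueError(f"insert must be exactly {inner} nt")
    seq = rand(flank[0]) + primers.forward + insert + rc + rand(flank[1])
    return SequenceRecord(
        id=template_id or f"synthetic_{primers.name}", seq=seq
    )


def synthetic_homeolog_templates(
    primers: PrimerPair,
    product_length: int,
    n_copies: int,
    *,
    seed: int = 0,
    copy_divergence: float = 0.05,
) -> list[SequenceRecord]:
    """Synthetic duplicated-gene copies sharing one identical primer region.

    Synthetic stand-ins for homeolog transcripts: all copies carry the same
    amplicon (primer sites and insert identical — the "identical region"
    a duplicated-gene primer pair targets), embedded in flanks that differ
    between copies and additionally diverge at ``copy_divergence`` of their
    positions, emulating the partial similarity of real gene copies.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    rc = primers.reverse_site
    inner = product_length - len(primers.forward) - len(rc)
    if inner < 0:
        raise ValueError("product_length shorter than the primer footprints")
    insert = "".join(rng.choice(bases, size=inner)) if inner else ""
    shared_flank5 = rng.choice(bases, size=60)
    shared_flank3 = rng.choice(bases, size=60)
    out = []
    for c in range(1, n_copies + 1):
        f5, f3 = shared_flank5.copy(), shared_flank3.copy()
        for arr in (f5, f3):
            hits = rng.random(len(arr)) < copy_divergence
            arr[hits] = rng.choice(bases, size=int(hits.sum()))
        seq = "".join(f5) + primers.forward + insert + rc + "".join(f3)
        out.append(
            SequenceRecord(id=f"synthetic_{primers.name}_copy{c}", seq=seq)
        )
    return out
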