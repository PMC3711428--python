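"""In-silico restriction cloning of engineered 5'-UTRs.

Reproduces the cloning scheme used to build the tuned reporter constructs:
RNA-motif duplexes are carried on a cassette flanked by a BamHI site (5')
and a BglII site (3'); ligating the compatible GATC overhangs of BamHI and
BglII yields a scar (AGATCC / GGATCT) cut by neither enzyme, so motifs can
be concatenated iteratively while the outer BamHI/BglII sites remain unique.
Spacer sequences (ATG-free) set the transcript coordinate of the first motif
base to a requested distance class (18, 67, 120, 164 or 320 nt from the +1
transcription start of the CMV promoter); the shortest class comes from a
NheI+BamHI digest, Klenow fill-in and self-ligation.

Double-stranded DNA is represented by its top strand plus the two
single-stranded 5'-overhang ends: ``five_prime_overhang`` is the
single-stranded prefix of the top strand at the left end, and
``three_prime_overhang`` is the acceptor at the right end -- the bases (in
top-strand orientation) that a ligating partner's 5' overhang must match.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .synthetic_flow import ConstructSpec

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _validate_bases(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"invalid bases in sequence: {sorted(bad)}")
    return seq


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class DNASequence:
    """Double-stranded DNA: top strand, topology, and sticky ends."""

    bases: str
    topology: str = "linear"
    five_prime_overhang: str = ""
    three_prime_overhang: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "bases", _validate_bases(self.bases))
        object.__setattr__(self, "five_prime_overhang",
                           _validate_bases(self.five_prime_overhang))
        object.__setattr__(self, "three_prime_overhang",
                           _validate_bases(self.three_prime_overhang))
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if len(self.five_prime_overhang) > 4 or len(self.three_prime_overhang) > 4:
            raise ValueError("overhangs longer than 4 nt are outside this "
                             "enzyme set")
        if self.topology == "circular" and (self.five_prime_overhang
                                            or self.three_prime_overhang):
            raise ValueError("circular DNA cannot carry overhangs")
        if self.five_prime_overhang and not self.bases.startswith(
                self.five_prime_overhang):
            raise ValueError("five_prime_overhang must be a prefix of the "
                             "top strand")

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def is_blunt(self) -> bool:
        return not self.five_prime_overhang and not self.three_prime_overhang


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A type-II enzyme cutting a palindromic site with a 5' overhang.

    ``cut_offset`` is the top-strand cut position within the site (0-based,
    counted from the site start); the overhang is the site slice between the
    top- and bottom-strand cuts.
    """

    name: str
    site: str
    cut_offset: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "site", _validate_bases(self.site))

    @property
    def overhang(self) -> str:
        """5' overhang sequence produced by the cut (top strand)."""
        return self.site[self.cut_offset:len(self.site) - self.cut_offset]


#: the enzyme set used by the cloning scheme (all palindromic, 5' overhangs)
ENZYMES = {
    "BamHI": RestrictionEnzyme("BamHI", "GGATCC", 1),     # G^GATCC -> GATC
    "BglII": RestrictionEnzyme("BglII", "AGATCT", 1),     # A^GATCT -> GATC
    "NheI": RestrictionEnzyme("NheI", "GCTAGC", 1),       # G^CTAGC -> CTAG
    "AgeI": RestrictionEnzyme("AgeI", "ACCGGT", 1),       # A^CCGGT -> CCGG
    "NcoI": RestrictionEnzyme("NcoI", "CCATGG", 1),       # C^CATGG -> CATG
    "SpeI": RestrictionEnzyme("SpeI", "ACTAGT", 1),       # A^CTAGT -> CTAG
    "NotI": RestrictionEnzyme("NotI", "GCGGCCGC", 2),     # GC^GGCCGC -> GGCC
    "HindIII": RestrictionEnzyme("HindIII", "AAGCTT", 1), # A^AGCTT -> AGCT
}


def _resolve(enzyme: "RestrictionEnzyme | str") -> RestrictionEnzyme:
    if isinstance(enzyme, RestrictionEnzyme):
        return enzyme
    try:
        return ENZYMES[enzyme]
    except KeyError:
        raise ValueError(f"enzyme {enzyme!r} is not in the packaged set "
                         f"({', '.join(ENZYMES)})") from None


# --------------------------------------------------------------------------
# Printed oligo duplexes and motif cores
# --------------------------------------------------------------------------

#: annealed duplex top strands for the cloning-vector cassettes.  Each reads
#: (NcoI-compatible CATG overhang)(BamHI site)(motif core)(A of the BglII
#: site reconstituted on ligation); the partner strand supplies the GATC
#: overhang at the 3' end.
MOTIF_DUPLEX_TOP = {
    "Kl": "CATGGGATCCGGGTGTGAACGGTGATCACCCGA",
    "Kl2": "CATGGGATCCGGACGTACGTGTGAACGGTGATCACGTACGCCGA",
    "MS2SL": "CATGGGATCCGGTGAGGATCACCCATCGA",
}

#: Fr15 is built by PCR from a printed template with printed primers, then
#: digested with NcoI and BglII.
FR15_TEMPLATE = ("GGGATGTCAGGTGCAGGCCAGACCGAAGTCCTCTCCTGCCCTCAAGTCTTTCGACC"
                 "ATCCCTATAGTGAGTCGTATTAGC")
FR15_PRIMER_FWD = "GCTAATCCATGGGATCCTCGGTCGAAAGACTTGAGGGC"
FR15_PRIMER_REV = "CCCAGATCTCGTCAGGTGCAGGCCAGAC"


@dataclass(frozen=True)
class MotifCassette:
    """A motif core flanked by one BamHI (5') and one BglII (3') site."""

    motif: str
    core: str
    copies: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "core", _validate_bases(self.core))
        if self.copies < 1:
            raise ValueError("copies must be >= 1")

    @property
    def sequence(self) -> str:
        """Top strand of the cassette in its vector context.

        k cores are separated by the 6-nt BamHI/BglII ligation scar
        (AGATCC); the outer ends remain one intact BamHI and one intact
        BglII site.
        """
        scar = "AGATCC"
        return ("GGATCC" + self.core
                + "".join(scar + self.core for _ in range(self.copies - 1))
                + "AGATCT")


def pcr_amplify(template: str, fwd_primer: str, rev_primer: str,
                min_anneal: int = 15) -> str:
    """Simulate PCR: primers anneal by their 3' ends; tails are appended.

    The template may be given as either strand.  Returns the top strand of
    the product, reading from the forward primer.
    """
    template = _validate_bases(template)
    fwd = _validate_bases(fwd_primer)
    rev = _validate_bases(rev_primer)
    for strand in (template, revcomp(template)):
        f3 = fwd[-min_anneal:]
        r3 = revcomp(rev[-min_anneal:])
        fpos = strand.find(f3)
        rpos = strand.find(r3)
        if fpos == -1 or rpos == -1 or rpos + len(r3) <= fpos + len(f3):
            continue
        middle = strand[fpos + len(f3):rpos]
        return fwd + middle + revcomp(rev)
    raise ValueError("primers do not anneal to the template in a productive "
                     "orientation")


def motif_cassette(motif: str, copies: int = 1) -> MotifCassette:
    """Build the cassette for a motif from its printed oligos/primers.

    The core is the printed duplex minus the flanking NcoI/BamHI/BglII
    cloning scaffold: the top strand between the BamHI site and the start of
    the reconstituted BglII site.
    """
    if motif in MOTIF_DUPLEX_TOP:
        seq = MOTIF_DUPLEX_TOP[motif] + "GATCT"  # ligated into a BglII site
    elif motif == "Fr15":
        seq = pcr_amplify(FR15_TEMPLATE, FR15_PRIMER_FWD, FR15_PRIMER_REV)
    else:
        raise ValueError(f"no printed cassette for motif {motif!r}")
    start = seq.index("GGATCC") + len("GGATCC")
    end = seq.rindex("AGATCT")
    core = seq[start:end]
    return MotifCassette(motif=motif, core=core, copies=copies)


# --------------------------------------------------------------------------
# Restriction / ligation operations
# --------------------------------------------------------------------------


def find_sites(seq: DNASequence, enzyme: "RestrictionEnzyme | str"
               ) -> list[int]:
    """1-based top-strand start positions of the recognition site.

    Circular sequences are scanned across the origin; positions are reported
    modulo the sequence length.
    """
    enz = _resolve(enzyme)
    text = seq.bases
    n = len(text)
    if seq.topology == "circular":
        text = text + text[:len(enz.site) - 1]
    positions = []
    start = 0
    while True:
        idx = text.find(enz.site, start)
        if idx == -1 or idx >= n:
            break
        positions.append(idx + 1)
        start = idx + 1
    return positions


def digest(seq: DNASequence,
           enzymes: "list[RestrictionEnzyme | str] | RestrictionEnzyme | str"
           ) -> list[DNASequence]:
    """Cut at every site of the given enzyme(s).

    Fragments carry the correct 5' overhangs; top-strand bases are conserved
    (each overhang's bases stay with the downstream fragment, and the
    upstream fragment records them as its right-end acceptor).  A sequence
    with no sites is returned unchanged (as a single fragment).
    """
    if isinstance(enzymes, (str, RestrictionEnzyme)):
        enzymes = [enzymes]
    enzs = [_resolve(e) for e in enzymes]

    cuts = []  # (top-strand cut index, overhang)
    for enz in enzs:
        for pos1 in find_sites(seq, enz):
            cut = pos1 - 1 + enz.cut_offset
            cuts.append((cut % len(seq.bases) if seq.topology == "circular"
                         else cut, enz.overhang))
    if not cuts:
        return [seq]
    cuts.sort()

    bases = seq.bases
    if seq.topology == "circular":
        # open the circle at the first cut
        first, _ = cuts[0]
        bases = bases[first:] + bases[:first]
        cuts = [(c - first, ov) for c, ov in cuts]
        left_end_overhang = cuts[0][1]
        bounds = [c for c, _ in cuts] + [len(bases)]
        overhangs = [ov for _, ov in cuts[1:]] + [left_end_overhang]
        fragments = []
        for i in range(len(cuts)):
            frag = bases[bounds[i]:bounds[i + 1]]
            left_ov = cuts[i][1]
            right_ov = overhangs[i]
            fragments.append(DNASequence(frag, "linear",
                                         five_prime_overhang=left_ov,
                                         three_prime_overhang=right_ov))
        return fragments

    fragments = []
    prev = 0
    prev_left = seq.five_prime_overhang
    for cut, ov in cuts:
        fragments.append(DNASequence(bases[prev:cut], "linear",
                                     five_prime_overhang=prev_left,
                                     three_prime_overhang=ov))
        prev, prev_left = cut, ov
    fragments.append(DNASequence(bases[prev:], "linear",
                                 five_prime_overhang=prev_left,
                                 three_prime_overhang=seq.three_prime_overhang))
    return fragments


def klenow_fill(seq: DNASequence) -> DNASequence:
    """Fill in 5' overhangs (Klenow), producing blunt ends.

    At the left end the recessed bottom strand is extended (top strand
    unchanged); at the right end the recessed top strand is extended by the
    acceptor bases.
    """
    return DNASequence(seq.bases + seq.three_prime_overhang, "linear")


def ligate(a: DNASequence, b: DNASequence, mode: str = "sticky"
           ) -> DNASequence:
    """Join the right end of ``a`` to the left end of ``b``.

    ``sticky`` requires the acceptor of ``a`` to match the 5' overhang of
    ``b`` exactly; ``blunt_after_fill`` fills both junction overhangs first
    (adding the acceptor bases of ``a`` and keeping the overhang prefix of
    ``b`` double-stranded).  The outer ends of the product keep their
    original chemistry.
    """
    if a.topology != "linear" or b.topology != "linear":
        raise ValueError("only linear fragments can be ligated end-to-end")
    if mode == "sticky":
        if a.three_prime_overhang != b.five_prime_overhang:
            raise ValueError(
                f"incompatible sticky ends: acceptor {a.three_prime_overhang!r}"
                f" vs overhang {b.five_prime_overhang!r}"
            )
        bases = a.bases + b.bases
    elif mode == "blunt_after_fill":
        bases = a.bases + a.three_prime_overhang + b.bases
    else:
        raise ValueError(f"unknown ligation mode {mode!r}")
    return DNASequence(bases, "linear",
                       five_prime_overhang=a.five_prime_overhang,
                       three_prime_overhang=b.three_prime_overhang)


def self_ligate(seq: DNASequence, mode: str = "sticky") -> DNASequence:
    """Circularize one fragment by joining its own two ends."""
    if mode == "sticky":
        if seq.three_prime_overhang != seq.five_prime_overhang:
            raise ValueError(
                f"incompatible ends for self-ligation: "
                f"{seq.three_prime_overhang!r} vs {seq.five_prime_overhang!r}"
            )
        return DNASequence(seq.bases, "circular")
    if mode == "blunt_after_fill":
        return DNASequence(klenow_fill(seq).bases, "circular")
    raise ValueError(f"unknown ligation mode {mode!r}")


def concatenate_motifs(cassette: MotifCassette, k: int) -> MotifCassette:
    """Concatenate k copies of the motif core via BamHI/BglII cycling.

    Each round excises the cassette with BamHI + BglII and re-inserts it
    into the BglII site of the growing clone; the GATC overhangs ligate into
    the AGATCC scar, leaving exactly one outer BamHI and one outer BglII
    site whatever k is.
    """
    if not 1 <= k <= 4:
        raise ValueError(f"copy number k={k} outside the supported range 1..4")
    return replace(cassette, copies=k)


# --------------------------------------------------------------------------
# 5'-UTR assembly
# --------------------------------------------------------------------------

#: reconstructed CMV +1 leader: the transcript bases upstream of the BamHI
#: cloning site.  The exact leader of the original vector is not published;
#: this 11-nt ATG-free stand-in is calibrated so that the shortest distance
#: class puts the first motif base at transcript position 18 (leader + BamHI
#: site + 1) and the motif-free control UTR is 32 nt long.
LEADER = "AGACCCAAGCT"
#: ATG-free 3' segment of the motif-free control UTR (synthetic stand-in;
#: brings the control 5'-UTR to its published 32-nt length: 11 + 21)
CONTROL_TAIL = "AGATCTCCACCGCCACCGCCA"
#: short ATG-free segment placed between the cassette's BglII site and the
#: start codon in assembled constructs
UTR_TAIL = "CCACC"

DISTANCE_CLASSES = (18, 67, 120, 164, 320)


def _atg_free_spacer(length: int, seed: int) -> str:
    """Deterministic ATG-free spacer of the requested length."""
    if length == 0:
        return ""
    rng = np.random.default_rng(seed)
    bases = "ACGT"
    for _attempt in range(1000):
        s = "".join(bases[i] for i in rng.integers(0, 4, size=length))
        if "ATG" not in s:
            return s
    raise RuntimeError("failed to draw an ATG-free spacer")  # pragma: no cover


def assemble_utr(distance_class: int | None, cassette: MotifCassette | None,
                 reporter: str = "ECFP", true_efficiency: float = 1.0,
                 seed: int = 0) -> tuple[ConstructSpec, DNASequence]:
    """Assemble a 5'-UTR with the first motif base at the requested position.

    Coordinates are 1-based on the transcript with the CMV transcription
    start at +1.  A seeded ATG-free spacer is inserted between the leader
    and the cassette so that ``leader + spacer + BamHI site`` ends exactly
    one base before the requested coordinate.  With no cassette the original
    32-nt control leader is returned.

    Returns the construct annotation and the UTR sequence (up to, not
    including, the initiation codon).
    """
    if cassette is None:
        utr = LEADER + CONTROL_TAIL
        spec = ConstructSpec(name=f"32 nt-control-{reporter}", motif="none",
                             distance_nt=32, copies=0, reporter=reporter,
                             true_efficiency=true_efficiency)
        return spec, DNASequence(utr)
    if distance_class is None or distance_class <= 0:
        raise ValueError("a positive distance class is required when a "
                         "cassette is given")

    min_d = len(LEADER) + len("GGATCC") + 1
    spacer_len = distance_class - min_d
    if spacer_len < 0:
        raise ValueError(
            f"distance class {distance_class} nt is unachievable: the leader "
            f"and BamHI site already span {min_d - 1} nt (minimum distance "
            f"{min_d})"
        )

    for attempt in range(100):
        spacer = _atg_free_spacer(spacer_len, seed + 1000 * attempt)
        utr = LEADER + spacer + cassette.sequence + UTR_TAIL
        # reject spacers whose junctions create an ATG outside the cores
        masked = utr.replace(cassette.core, "N" * len(cassette.core))
        if "ATG" not in masked:
            break
    else:  # pragma: no cover
        raise RuntimeError("could not build an ATG-free context")

    name = f"{distance_class} nt-{cassette.copies}x {cassette.motif}-{reporter}"
    spec = ConstructSpec(name=name, motif=cassette.motif,
                         distance_nt=distance_class, copies=cassette.copies,
                         reporter=reporter, true_efficiency=true_efficiency)
    return spec, DNASequence(utr)


def motif_offset(utr: DNASequence, cassette: MotifCassette) -> int | None:
    """1-based position of the first motif-core base in the UTR, or None."""
    idx = utr.bases.find(cassette.core)
    return idx + 1 if idx >= 0 else None


def all_motif_offsets(utr: DNASequence, cassette: MotifCassette) -> list[int]:
    """1-based positions of every (non-overlapping) core occurrence."""
    positions, start = [], 0
    while True:
        idx = utr.bases.find(cassette.core, start)
        if idx == -1:
            return positions
        positions.append(idx + 1)
        start = idx + len(cassette.core)


# --------------------------------------------------------------------------
# FASTA / annotation export
# --------------------------------------------------------------------------


def write_fasta(records: "list[tuple[str, DNASequence]]", path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    seqrecords = [SeqRecord(Seq(seq.bases), id=name.replace(" ", "_"),
                            description="") for name, seq in records]
    SeqIO.write(seqrecords, str(path), "fasta")


def read_fasta(path) -> "list[tuple[str, DNASequence]]":
    from Bio import SeqIO

    return [(rec.id, DNASequence(str(rec.seq)))
            for rec in SeqIO.parse(str(path), "fasta")]
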