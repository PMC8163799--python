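"""Surrogate library design: guide finding, oligo assembly, cloning screens.

Each library member couples a 20-nt spacer with a 37-bp surrogate copy of
its genomic target (10 bp upstream + 20 bp protospacer + 3 bp PAM + 4 bp
downstream) on a single 170-bp synthetic oligo, so editing outcomes can be
read out by amplicon sequencing of the surrogate.  Oligos are assembled
for Golden-Gate cloning with BsmBI, which is why candidate surrogates
containing a BsmBI recognition site are screened out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .features import GuideContext, build_context, _check_seq, LengthError

COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(COMP)[::-1]


BSMBI = "CGTCTC"
BSMBI_RC = revcomp(BSMBI)  # GAGACG

# Fixed oligo linkers (case preserved from the synthesis design for
# traceability; all comparisons are case-insensitive).
PREFIX = "acca"
CLONING_LINKER = "aCACC"
U6_G = "g"
DOWNSTREAM_LINKER = "GTTTg"
SUFFIX = "acgg"

# Default 82-nt SpCas9 sgRNA scaffold: the canonical 76-nt scaffold
# followed by a 6-T pol-III terminator.  Configurable; only the length
# is contractual.
DEFAULT_SCAFFOLD = (
    "GTTTTAGAGCTAGAAATAGCAAGTTAAAATAAGGCTAGTCCGTTATCAACTTGAAAAAGTGGCACCGAGTCGGTGC"
    + "TTTTTT"
)
assert len(DEFAULT_SCAFFOLD) == 82


@dataclass(frozen=True)
class SurrogateSite:
    """37-bp surrogate target: 10 up + 20 protospacer + 3 PAM + 4 down."""

    up10: str
    protospacer: str
    pam: str
    down4: str

    def __post_init__(self):
        for name, want in (("up10", 10), ("protospacer", 20), ("pam", 3), ("down4", 4)):
            seq = getattr(self, name)
            if len(seq) != want:
                raise LengthError(f"{name} must be {want} nt, got {len(seq)}")

    @property
    def seq37(self) -> str:
        return self.up10 + self.protospacer + self.pam + self.down4


@dataclass(frozen=True)
class OligoRecord:
    spacer: str
    surrogate: SurrogateSite
    oligo: str
    flags: frozenset = field(default_factory=frozenset)


@dataclass(frozen=True)
class GuideHit:
    """One NGG site found on a design target sequence."""

    context: GuideContext
    surrogate: SurrogateSite
    strand: str
    start: int  # protospacer coordinates on the input, 0-based half-open
    end: int


def find_guides(sequence: str, min_up: int = 10, min_down: int = 4) -> list[GuideHit]:
    """All 20-nt protospacers followed by NGG on either strand.

    Hits need ``min_up`` bases upstream of the protospacer and
    ``min_down`` bases downstream of the PAM on their own strand (the
    surrogate flanks); sites too close to an end are skipped.  Reverse
    strand hits are reported in protospacer orientation with 0-based,
    half-open coordinates on the forward input sequence.
    """
    seq = _check_seq(sequence, "sequence")
    n = len(seq)
    hits: list[GuideHit] = []
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for i in range(n - 22):
            pam = s[i + 20:i + 23]
            if pam[1:3] != "GG":
                continue
            if i < min_up or i + 23 + min_down > n:
                continue
            proto = s[i:i + 20]
            surrogate = SurrogateSite(s[i - 10:i], proto, pam, s[i + 23:i + 27])
            ctx = build_context(s[i - 4:i], proto, pam, s[i + 23:i + 26],
                                strand=strand,
                                start=i if strand == "+" else n - i - 20,
                                end=i + 20 if strand == "+" else n - i)
            hits.append(GuideHit(ctx, surrogate, strand, ctx.start, ctx.end))
    return hits


def bsmbi_screen(site: SurrogateSite) -> bool:
    """True (pass) iff seq37 contains no BsmBI site on either strand."""
    s = site.seq37.upper()
    return BSMBI not in s and BSMBI_RC not in s


def assemble_oligo(spacer: str, surrogate: SurrogateSite,
                   scaffold: str = DEFAULT_SCAFFOLD) -> OligoRecord:
    """Assemble the 170-bp synthesis oligo.

    Layout: acca + cgtctc (BsmBI) + aCACC + g + spacer(20) + scaffold(82)
    + surrogate(37) + GTTTg + gagacg (BsmBI, reverse orientation) + acgg
    = 4+6+5+1+20+82+37+5+6+4 = 170 bp.
    """
    spacer = _check_seq(spacer, "spacer")
    if len(spacer) != 20:
        raise LengthError(f"spacer must be 20 nt, got {len(spacer)}")
    if len(scaffold) != 82:
        raise LengthError(f"scaffold must be 82 nt, got {len(scaffold)}")
    oligo = (PREFIX + BSMBI.lower() + CLONING_LINKER + U6_G + spacer + scaffold
             + surrogate.seq37 + DOWNSTREAM_LINKER + BSMBI_RC.lower() + SUFFIX)
    flags = set()
    if not bsmbi_screen(surrogate):
        flags.add("bsmbi_clash")
    if surrogate.pam[1:3] != "GG":
        flags.add("non_canonical_pam")
    return OligoRecord(spacer, surrogate, oligo, frozenset(flags))


def parse_oligo(oligo: str) -> tuple[str, SurrogateSite]:
    """Recover (spacer, surrogate) from a 170-bp oligo; inverse of assembly."""
    if len(oligo) != 170:
        raise LengthError(f"oligo must be 170 bp, got {len(oligo)}")
    up = oligo.upper()
    head = (PREFIX + BSMBI + CLONING_LINKER + U6_G).upper()
    if up[:16] != head or up[-15:-10] != DOWNSTREAM_LINKER.upper():
        raise ValueError("oligo linkers do not match the fixed layout")
    spacer = up[16:36]
    seq37 = up[118:155]
    site = SurrogateSite(seq37[:10], seq37[10:30], seq37[30:33], seq37[33:])
    return spacer, site
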