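"""Sequence feature encodings for gRNA + context 30mers.

The model input window is a 30-nt DNA sequence: 4 nt upstream flank,
the 20-nt protospacer, the 3-nt PAM, and 3 nt downstream of the PAM.
Positions are 1-based on the 30mer (PAM at 25-27); protospacer positions
are numbered N1 (PAM-distal) to N20 (PAM-proximal), so N17 sits 4 bp
upstream of the PAM.

Three representations are produced:

* one-hot matrices/vectors (channel order A, C, G, T; flattening is
  position-major), used by the convolutional model and for Hamming
  distances — two sequences differing at m positions are 2*m apart in
  one-hot space;
* position-specific single/dinucleotide indicators plus NGGX flanking
  indicators;
* composition counts, protospacer GC count, segment melting
  temperatures, spacer folding energy and the binding energy dGB.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ALPHABET = "ACGT"
_CHANNEL = {c: i for i, c in enumerate(ALPHABET)}
DINUCLEOTIDES = tuple(a + b for a in ALPHABET for b in ALPHABET)


class AlphabetError(ValueError):
    """Sequence contains a symbol outside {A, C, G, T}."""


class LengthError(ValueError):
    """Sequence segment has the wrong length."""


def _check_seq(seq: str, name: str = "sequence") -> str:
    seq = seq.upper()
    if not seq:
        raise LengthError(f"{name} is empty")
    bad = set(seq) - set(ALPHABET)
    if bad:
        raise AlphabetError(f"{name} contains non-ACGT symbols: {sorted(bad)}")
    return seq


@dataclass(frozen=True)
class GuideContext:
    """A validated 30-nt gRNA + context record (4 + 20 + 3 + 3)."""

    upstream: str
    protospacer: str
    pam: str
    downstream: str
    id: str = ""
    strand: str = "+"
    start: int | None = None  # 0-based, half-open, protospacer on source
    end: int | None = None

    @property
    def full30(self) -> str:
        return self.upstream + self.protospacer + self.pam + self.downstream

    @property
    def canonical(self) -> bool:
        """True iff the PAM is 5'-NGG-3'."""
        return self.pam[1:3] == "GG"

    @property
    def spacer_rna(self) -> str:
        """The 20-nt gRNA spacer (transcript of the protospacer)."""
        return self.protospacer.replace("T", "U")


def build_context(upstream: str, protospacer: str, pam: str, downstream: str,
                  id: str = "", strand: str = "+",
                  start: int | None = None, end: int | None = None) -> GuideContext:
    """Validate segment lengths/alphabet and assemble a :class:`GuideContext`."""
    parts = {"upstream": (upstream, 4), "protospacer": (protospacer, 20),
             "pam": (pam, 3), "downstream": (downstream, 3)}
    clean = {}
    for name, (seq, want) in parts.items():
        seq = _check_seq(seq, name)
        if len(seq) != want:
            raise LengthError(f"{name} must be {want} nt, got {len(seq)}")
        clean[name] = seq
    return GuideContext(clean["upstream"], clean["protospacer"], clean["pam"],
                        clean["downstream"], id=id, strand=strand, start=start, end=end)


def one_hot(seq: str) -> np.ndarray:
    """One-hot encode an ACGT string as a 4 x L binary matrix (rows A,C,G,T)."""
    seq = _check_seq(seq)
    mat = np.zeros((4, len(seq)), dtype=np.int8)
    for j, c in enumerate(seq):
        mat[_CHANNEL[c], j] = 1
    return mat


def one_hot_flat(seq: str) -> np.ndarray:
    """Position-major flattening of :func:`one_hot`: length 4*L (120 for 30mers)."""
    return one_hot(seq).T.ravel()


def decode_one_hot(mat: np.ndarray) -> str:
    """Inverse of :func:`one_hot` (argmax per column)."""
    return "".join(ALPHABET[i] for i in np.asarray(mat).argmax(axis=0))


def onehot_hamming(a: np.ndarray, b: np.ndarray) -> int:
    """Hamming distance between two one-hot encodings (matrix or flat).

    Equals twice the number of mismatching sequence positions.
    """
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if a.shape != b.shape:
        raise ValueError(f"one-hot encodings differ in size: {a.size} vs {b.size}")
    return int(np.count_nonzero(a != b))


def seq_mismatches(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    return sum(x != y for x, y in zip(a, b))


# ---------------------------------------------------------------------------
# Named feature vector

def feature_names() -> list[str]:
    """Stable ordering of the full feature vector."""
    names = [f"{n}_{x}" for x in range(1, 31) for n in ALPHABET]
    names += [f"{d}_{x}" for x in range(1, 30) for d in DINUCLEOTIDES]
    names += [f"NGGX_{d}" for d in DINUCLEOTIDES]
    names += list(ALPHABET) + list(DINUCLEOTIDES)
    names += ["gc_count", "mt_3_7", "mt_8_15", "mt_16_20", "fold_energy", "dGB"]
    return names


def feature_vector(g: GuideContext, thermo) -> dict[str, float]:
    """Complete named feature mapping for one guide.

    ``thermo`` is the :class:`~guideeff.thermo.EnergyProfile` computed for
    the same guide; it contributes the three segment melting temperatures,
    the spacer folding energy and dGB.
    """
    s = g.full30
    feats: dict[str, float] = {}
    for x in range(1, 31):
        for n in ALPHABET:
            feats[f"{n}_{x}"] = 1.0 if s[x - 1] == n else 0.0
    for x in range(1, 30):
        di = s[x - 1:x + 1]
        for d in DINUCLEOTIDES:
            feats[f"{d}_{x}"] = 1.0 if di == d else 0.0
    # NGGX: nucleotides flanking the canonical GG of the PAM (30mer pos 25
    # = protospacer N20, and pos 28).  All-zero for non-canonical PAMs.
    yz = s[24] + s[27] if g.canonical else None
    for d in DINUCLEOTIDES:
        feats[f"NGGX_{d}"] = 1.0 if yz == d else 0.0
    for n in ALPHABET:
        feats[n] = float(s.count(n))
    for d in DINUCLEOTIDES:
        feats[d] = float(sum(1 for i in range(29) if s[i:i + 2] == d))
    feats["gc_count"] = float(g.protospacer.count("G") + g.protospacer.count("C"))
    feats["mt_3_7"] = float(thermo.mt_3_7)
    feats["mt_8_15"] = float(thermo.mt_8_15)
    feats["mt_16_20"] = float(thermo.mt_16_20)
    feats["fold_energy"] = float(thermo.fold_energy)
    feats["dGB"] = float(thermo.dGB)
    return feats


def feature_frame(mer30s, ids=None):
    """Full feature table (one row per 30mer) as a pandas DataFrame.

    Computes the energy profile for each guide with the default
    parameter set and folding backend.
    """
    import pandas as pd

    from .thermo import energy_profile, load_default_params

    params = load_default_params()
    rows = []
    for i, m in enumerate(mer30s):
        g = build_context(m[:4], m[4:24], m[24:27], m[27:30],
                          id=ids[i] if ids is not None else f"g{i}")
        rows.append(feature_vector(g, energy_profile(g, params)))
    df = pd.DataFrame(rows, columns=feature_names())
    if ids is not None:
        df.insert(0, "guide_id", list(ids))
    return df
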