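"""Thermodynamic features: melting temperatures, spacer folding, and dGB.

The binding energy dGB summarises how favourably a gRNA engages its
target as a three-term decomposition::

    dGB = -(dG_hyb + dG_open + dG_unfold)

* ``dG_hyb``    nearest-neighbor free energy of forming the 20-bp
  RNA:DNA hybrid (negative when favourable; Sugimoto et al. 1995
  parameters);
* ``dG_open``   penalty for opening the genomic DNA:DNA duplex over the
  protospacer, taken as minus the duplex free energy (SantaLucia 1998
  unified parameters), hence >= 0;
* ``dG_unfold`` penalty for unfolding pre-formed spacer secondary
  structure, taken as minus the spacer folding free energy, hence >= 0.

Larger dGB means more stable binding.  All free energies are kcal/mol at
37 C; the dimer tables ship as plain-text data files alongside the
package.  Segment melting temperatures use the nearest-neighbor Tm from
Biopython at fixed default salt/strand conditions (50 mM Na+, 25 nM each
strand), recorded in :data:`TM_CONDITIONS`.

Spacer folding defaults to a built-in simplified folder that scores
Watson-Crick hairpin stems (stack energies + loop penalty) and reports
the best (most negative) hairpin energy, 0 for structure-free sequences.
An adapter for an external folding program (e.g. RNAfold) is provided
for users who want partition-function fidelity.
"""

from __future__ import annotations

import math
import shutil
import subprocess
from dataclasses import dataclass
from importlib import resources

from Bio.SeqUtils import MeltingTemp as _mt

from .features import GuideContext, _check_seq

T_REF = 310.15  # 37 C in K

TM_CONDITIONS = {"Na_mM": 50.0, "dnac1_nM": 25.0, "dnac2_nM": 25.0, "nn_table": "SantaLucia 1998 (unified)"}


class ParameterError(KeyError):
    """A required nearest-neighbor dimer parameter is missing."""


class BackendError(RuntimeError):
    """The folding backend failed to produce a free energy."""


@dataclass(frozen=True)
class EnergyProfile:
    """dGB and its components plus auxiliary thermodynamic features."""

    dG_hyb: float
    dG_open: float
    dG_unfold: float
    fold_energy: float
    mt_3_7: float
    mt_8_15: float
    mt_16_20: float

    @property
    def dGB(self) -> float:
        return -(self.dG_hyb + self.dG_open + self.dG_unfold)


class NNParameterSet:
    """Dimer -> (dH, dS, dG37) tables for DNA:DNA and RNA:DNA duplexes."""

    def __init__(self, dna_dna: dict[str, tuple[float, float]],
                 rna_dna: dict[str, tuple[float, float]],
                 dna_init: dict[str, tuple[float, float]],
                 rna_init: tuple[float, float],
                 salt: str = "1 M NaCl"):
        for name, table in (("DNA:DNA", dna_dna), ("RNA:DNA", rna_dna)):
            missing = {a + b for a in "ACGT" for b in "ACGT"} - set(table)
            if missing:
                raise ParameterError(f"{name} table missing dimers: {sorted(missing)}")
        self.dna_dna = dna_dna
        self.rna_dna = rna_dna
        self.dna_init = dna_init
        self.rna_init = rna_init
        self.salt = salt

    @staticmethod
    def dg37(dh: float, ds: float) -> float:
        """dG at 37 C from dH (kcal/mol) and dS (cal/mol/K)."""
        return dh - T_REF * ds / 1000.0

    def hybrid_dg(self, protospacer: str) -> float:
        """RNA:DNA hybrid free energy for the transcript of ``protospacer``."""
        dh, ds = self.rna_init
        for i in range(len(protospacer) - 1):
            d = protospacer[i:i + 2]
            h, s = self.rna_dna[d]
            dh += h
            ds += s
        return self.dg37(dh, ds)

    def duplex_dg(self, seq: str) -> float:
        """DNA:DNA duplex free energy of ``seq`` against its complement."""
        dh, ds = 0.0, 0.0
        for term in (seq[0], seq[-1]):
            h, s = self.dna_init["init_GC" if term in "GC" else "init_AT"]
            dh += h
            ds += s
        for i in range(len(seq) - 1):
            h, s = self.dna_dna[seq[i:i + 2]]
            dh += h
            ds += s
        return self.dg37(dh, ds)


def _read_table(name: str) -> dict[str, tuple[float, float]]:
    text = resources.files("guideeff.data").joinpath(name).read_text()
    out = {}
    for line in text.splitlines():
        if not line or line.startswith("#") or line.startswith("dimer"):
            continue
        key, dh, ds = line.split("\t")
        out[key] = (float(dh), float(ds))
    return out


_DEFAULT_PARAMS: NNParameterSet | None = None


def load_default_params() -> NNParameterSet:
    """Load the bundled SantaLucia 1998 / Sugimoto 1995 parameter set."""
    global _DEFAULT_PARAMS
    if _DEFAULT_PARAMS is None:
        dna = _read_table("dna_dna_nn.tsv")
        rna = _read_table("rna_dna_nn.tsv")
        dna_init = {k: dna.pop(k) for k in ("init_AT", "init_GC")}
        rna_init = rna.pop("init")
        _DEFAULT_PARAMS = NNParameterSet(dna, rna, dna_init, rna_init)
    return _DEFAULT_PARAMS


# ---------------------------------------------------------------------------
# Melting temperatures

def melting_temperatures(protospacer: str, params: NNParameterSet | None = None) -> tuple[float, float, float]:
    """Nearest-neighbor Tm (C) of protospacer segments 3-7, 8-15, 16-20 (1-based)."""
    protospacer = _check_seq(protospacer, "protospacer")
    if len(protospacer) != 20:
        raise ValueError(f"protospacer must be 20 nt, got {len(protospacer)}")
    segs = (protospacer[2:7], protospacer[7:15], protospacer[15:20])
    return tuple(
        float(_mt.Tm_NN(s, nn_table=_mt.DNA_NN3,
                        Na=TM_CONDITIONS["Na_mM"],
                        dnac1=TM_CONDITIONS["dnac1_nM"],
                        dnac2=TM_CONDITIONS["dnac2_nM"]))
        for s in segs
    )


# ---------------------------------------------------------------------------
# Spacer folding backends

_RNA_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}

# Watson-Crick stack free energies (kcal/mol, 37 C), keyed by the 5' strand
# dimer of the stack; symmetric partner obtained by RNA reverse complement.
_RNA_STACK = {
    "AA": -0.93, "AU": -1.10, "UA": -1.33, "CU": -2.08, "CA": -2.11,
    "GU": -2.24, "GA": -2.35, "CG": -2.36, "GG": -3.26, "GC": -3.42,
    "UU": -0.93, "UG": -2.11, "AG": -2.08, "UC": -2.35, "CC": -3.26, "AC": -2.24,
}
# Hairpin loop initiation penalties by loop length.
_LOOP_DG = {3: 5.4, 4: 5.6, 5: 5.7, 6: 5.4, 7: 6.0, 8: 5.5, 9: 6.4}
_RT37 = 0.616


def _loop_penalty(n: int) -> float:
    if n in _LOOP_DG:
        return _LOOP_DG[n]
    return _LOOP_DG[9] + 1.75 * _RT37 * math.log(n / 9.0)


def _wc(a: str, b: str) -> bool:
    return _RNA_COMP[a] == b


class HairpinFolder:
    """Built-in simplified spacer folder.

    Scores every Watson-Crick hairpin (stem of stacked pairs around a
    loop of >= ``min_loop`` nt) as the sum of its stack energies plus the
    loop penalty and returns the minimum, capped at 0 for sequences with
    no stabilising structure.  Multi-branch structures, internal loops
    and wobble pairs are not modelled.
    """

    min_loop = 3

    def fold(self, rna: str) -> float:
        n = len(rna)
        best = 0.0
        for i in range(n):
            for j in range(i + self.min_loop + 1, n):
                if not _wc(rna[i], rna[j]):
                    continue
                # innermost pair (i, j); extend the stem outwards
                energy = _loop_penalty(j - i - 1)
                k = 1
                while i - k >= 0 and j + k < n and _wc(rna[i - k], rna[j + k]):
                    energy += _RNA_STACK[rna[i - k] + rna[i - k + 1]]
                    k += 1
                    best = min(best, energy)
        return best


class ExternalFolder:
    """Adapter for an external folding program (RNAfold-style contract).

    The program receives the RNA sequence on standard input and must
    print a line containing the free energy in parentheses, e.g.
    ``((((...)))) (-4.20)``.
    """

    def __init__(self, command: str = "RNAfold", args: tuple[str, ...] = ("--noPS",)):
        self.command = command
        self.args = args

    def fold(self, rna: str) -> float:
        exe = shutil.which(self.command)
        if exe is None:
            raise BackendError(f"folding program not found: {self.command}")
        try:
            out = subprocess.run([exe, *self.args], input=rna + "\n", text=True,
                                 capture_output=True, check=True, timeout=60).stdout
        except (subprocess.CalledProcessError, subprocess.TimeoutExpired) as exc:
            raise BackendError(f"{self.command} failed: {exc}") from exc
        for line in reversed(out.splitlines()):
            if "(" in line and ")" in line:
                token = line[line.rfind("("):].strip("() \t")
                try:
                    return float(token)
                except ValueError:
                    continue
        raise BackendError(f"could not parse free energy from {self.command} output: {out!r}")


def spacer_fold_energy(spacer, backend=None) -> float:
    """Folding free energy (kcal/mol, <= 0) of a 20-nt spacer RNA.

    ``spacer`` may be given in RNA or DNA alphabet.  ``backend`` is any
    object with a ``fold(rna) -> float`` method; defaults to the built-in
    :class:`HairpinFolder`.
    """
    rna = spacer.upper().replace("T", "U")
    if len(rna) != 20:
        raise ValueError(f"spacer must be 20 nt, got {len(rna)}")
    bad = set(rna) - set("ACGU")
    if bad:
        raise ValueError(f"spacer contains non-ACGU symbols: {sorted(bad)}")
    backend = backend or HairpinFolder()
    energy = float(backend.fold(rna))
    return min(energy, 0.0)


# ---------------------------------------------------------------------------
# Binding energy

def binding_energy(target: GuideContext, params: NNParameterSet | None = None,
                   backend=None) -> EnergyProfile:
    """Full :class:`EnergyProfile` for a guide, assuming a perfect-match spacer."""
    params = params or load_default_params()
    proto = target.protospacer
    dg_hyb = params.hybrid_dg(proto)
    dg_open = max(0.0, -params.duplex_dg(proto))
    fold = spacer_fold_energy(proto, backend=backend)
    mt3, mt8, mt16 = melting_temperatures(proto, params)
    return EnergyProfile(dG_hyb=dg_hyb, dG_open=dg_open, dG_unfold=-fold,
                         fold_energy=fold, mt_3_7=mt3, mt_8_15=mt8, mt_16_20=mt16)


# The complete profile and the binding-energy computation coincide here:
# dGB needs all three terms anyway, so one pass produces everything.
energy_profile = binding_energy
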