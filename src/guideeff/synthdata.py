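"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the statistical structure of a massively parallel
surrogate screen without claiming to be the true sequence-activity
relationship: planted efficiency is a logistic-bounded linear function
of GC content, binding energy dGB and spacer folding, penalized outside
the favourable 40-90% protospacer GC window and below a -7.5 kcal/mol
folding energy; paired measurement days are the truth plus independent
noise calibrated to a requested between-day Pearson correlation; read
libraries carry deterministically rounded edit counts so quantification
can be checked for exact recovery; and dataset pairs for fusion are
related by a known linear transform on a small overlap.

Every generator output carries its truth table; downstream tests read
truth only from there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import build_context
from .librarydesign import DEFAULT_SCAFFOLD, SurrogateSite
from .ampliconquant import LINKER_SIGNATURE
from .thermo import energy_profile, load_default_params

# Reference moments of dGB / fold energy over random 20-nt protospacers,
# used to place the planted covariates on comparable scales.
DGB_REF = (-0.5, 2.1)
FOLD_REF = (-0.3, 0.85)


@dataclass(frozen=True)
class GeneratorSpec:
    """Study conditions for the synthetic screen."""

    n_guides: int = 2000
    seed: int = 0
    # planted effect weights (logit units)
    w_gc: float = 1.2
    w_dgb: float = 1.0
    w_fold: float = 0.3
    w_pos: float = 0.4           # PAM-proximal G favoured, T disfavoured
    gc_window: tuple = (0.40, 0.90)
    gc_penalty: float = 1.5
    mfe_threshold: float = -7.5   # kcal/mol
    mfe_penalty: float = 1.0
    # replicate structure
    noise_sd: float | None = None        # percent; overrides day_correlation
    day_correlation: float = 0.91
    # dataset-pair / fusion structure
    reference_ratio: float = 13359 / 10592
    overlap_fraction: float = 49 / 10592
    fusion_slope: float = 0.8
    fusion_intercept: float = 7.0
    fusion_noise_sd: float = 0.0
    # read libraries
    read_depth: int = 1000
    background_rate: float = 0.05
    insertion_templating: float = 0.8
    stochastic_reads: bool = False

    def __post_init__(self):
        if self.n_guides < 1:
            raise ValueError("n_guides must be >= 1")
        if self.day_correlation is not None and not (0 < self.day_correlation <= 1):
            raise ValueError("day_correlation must be in (0, 1]")
        for p in (self.background_rate, self.insertion_templating, self.overlap_fraction):
            if not (0 <= p <= 1):
                raise ValueError("probabilities must be in [0, 1]")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def _random_guides(rng: np.random.Generator, n: int) -> list[str]:
    """Unique random 30mers with a canonical NGG PAM (positions 26-27)."""
    seen: set[str] = set()
    out: list[str] = []
    bases = np.array(list("ACGT"))
    while len(out) < n:
        chars = bases[rng.integers(0, 4, size=30)]
        chars[25] = "G"
        chars[26] = "G"
        s = "".join(chars)
        if s not in seen:
            seen.add(s)
            out.append(s)
    return out


def gen_guides(spec: GeneratorSpec, seed: int | None = None) -> pd.DataFrame:
    """Guide panel with planted truth and two noisy measurement days.

    Columns include the 30mer and its segments, the thermodynamic
    covariates, ``true_efficiency`` (noise-free, percent) and
    ``efficiency_day8`` / ``efficiency_day10`` replicates plus their
    mean ``efficiency``.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    params = load_default_params()
    mers = _random_guides(rng, spec.n_guides)
    rows = []
    for i, m in enumerate(mers):
        g = build_context(m[:4], m[4:24], m[24:27], m[27:30], id=f"g{i:05d}")
        prof = energy_profile(g, params)
        rows.append({
            "guide_id": g.id, "mer30": m, "upstream": g.upstream,
            "protospacer": g.protospacer, "pam": g.pam, "downstream": g.downstream,
            "gc_count": g.protospacer.count("G") + g.protospacer.count("C"),
            "dGB": prof.dGB, "fold_energy": prof.fold_energy,
            "mt_3_7": prof.mt_3_7, "mt_8_15": prof.mt_8_15, "mt_16_20": prof.mt_16_20,
            "n20": g.protospacer[19],
        })
    df = pd.DataFrame(rows)

    gc_frac = df["gc_count"].to_numpy() / 20.0
    dgb_z = (df["dGB"].to_numpy() - DGB_REF[0]) / DGB_REF[1]
    fold_z = (df["fold_energy"].to_numpy() - FOLD_REF[0]) / FOLD_REF[1]
    z = (spec.w_gc * (gc_frac - 0.5) / 0.11
         + spec.w_dgb * dgb_z
         + spec.w_fold * fold_z
         + spec.w_pos * (df["n20"].eq("G").to_numpy().astype(float)
                         - df["n20"].eq("T").to_numpy().astype(float)))
    lo, hi = spec.gc_window
    z = z - spec.gc_penalty * ((gc_frac < lo) | (gc_frac > hi))
    z = z - spec.mfe_penalty * (df["fold_energy"].to_numpy() < spec.mfe_threshold)
    truth = 100.0 * _sigmoid(z)
    df["true_efficiency"] = truth

    if spec.noise_sd is not None:
        sd = spec.noise_sd
    elif spec.day_correlation is not None and spec.day_correlation < 1:
        var_t = float(np.var(truth))
        sd = float(np.sqrt(var_t * (1.0 / spec.day_correlation - 1.0)))
    else:
        sd = 0.0
    df["efficiency_day8"] = np.clip(truth + rng.normal(0, sd, truth.size), 0, 100) if sd else truth
    df["efficiency_day10"] = np.clip(truth + rng.normal(0, sd, truth.size), 0, 100) if sd else truth
    df["efficiency"] = (df["efficiency_day8"] + df["efficiency_day10"]) / 2.0
    df["read_support"] = spec.read_depth
    df.attrs["noise_sd"] = sd
    return df


def gen_dataset_pair(spec: GeneratorSpec, seed: int | None = None):
    """(source, reference) datasets related by a linear transform on overlaps.

    The reference efficiencies on the overlapping 30mers equal
    ``fusion_slope * source + fusion_intercept`` plus optional noise;
    reference-only guides carry independent efficiencies.  Returns
    ``(source, reference, truth)`` with the overlap bookkeeping.
    """
    if not (0 < spec.overlap_fraction < 1):
        raise ValueError("overlap_fraction must be in (0, 1)")
    base_seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(base_seed + 1)
    source = gen_guides(spec, seed=base_seed)
    n_overlap = max(2, round(spec.overlap_fraction * spec.n_guides))
    n_ref_only = max(0, round(spec.reference_ratio * spec.n_guides) - n_overlap)
    overlap_idx = rng.choice(spec.n_guides, size=n_overlap, replace=False)
    overlap = source.iloc[overlap_idx][["guide_id", "mer30", "efficiency"]].copy()
    ref_eff = spec.fusion_slope * overlap["efficiency"].to_numpy() + spec.fusion_intercept
    if spec.fusion_noise_sd:
        ref_eff = ref_eff + rng.normal(0, spec.fusion_noise_sd, ref_eff.size)
    overlap["efficiency"] = ref_eff

    from dataclasses import replace as _replace
    ref_spec = _replace(spec, n_guides=max(1, n_ref_only))
    ref_only = gen_guides(ref_spec, seed=base_seed + 7)[["guide_id", "mer30", "efficiency"]]
    ref_only = ref_only[~ref_only["mer30"].isin(set(source["mer30"]))]
    ref_only["guide_id"] = [f"r{i:05d}" for i in range(len(ref_only))]
    reference = pd.concat([overlap, ref_only], ignore_index=True)
    truth = {"n_overlap": n_overlap, "slope": spec.fusion_slope,
             "intercept": spec.fusion_intercept,
             "overlap_mer30": set(overlap["mer30"])}
    return source, reference, truth


# ---------------------------------------------------------------------------
# Read libraries with planted indel profiles

# Planted indel class mix (conditional on a read being edited):
# 1-bp insertions dominate, deletions decay with size.
def _class_mix() -> list[tuple[str, int, float]]:
    classes = [("ins", 1, 0.30)]
    for s in range(2, 11):
        classes.append(("ins", s, 0.02 * 0.6 ** (s - 2)))
    w = 0.22
    for s in range(1, 31):
        classes.append(("del", s, w))
        w *= 0.78
    total = sum(c[2] for c in classes)
    return [(k, s, p / total) for k, s, p in classes]


CLASS_MIX = _class_mix()


def _del_window(ref: str, size: int) -> str:
    cut = 27  # blunt cut: 10-nt flank + 17 protospacer bases
    start = max(0, min(cut - size // 2, len(ref) - size))
    return ref[:start] + ref[start + size:]


def _ins_window(ref: str, size: int, base: str) -> str:
    cut = 27
    return ref[:cut] + base * size + ref[cut:]


def _largest_remainder(probs: np.ndarray, total: int) -> np.ndarray:
    exact = probs * total
    counts = np.floor(exact).astype(np.int64)
    rem = total - counts.sum()
    if rem > 0:
        order = np.argsort(-(exact - np.floor(exact)))
        counts[order[:rem]] += 1
    return counts


def _background_variant(ref: str, edited: set[str]) -> str:
    """A length-changing synthesis-artifact window distinct from any edit."""
    for pos in range(1, len(ref) - 2):
        cand = ref[:pos] + ref[pos + 2:]
        if cand not in edited:
            return cand
    return ref[:-3]  # degenerate fallback


def gen_windows(spec: GeneratorSpec, libraries: dict[str, SurrogateSite],
                efficiencies: dict[str, float] | None = None, seed: int | None = None):
    """Per-library surrogate windows with planted edits.

    Edited windows follow :data:`CLASS_MIX`; counts are planted by
    deterministic largest-remainder rounding at ``read_depth`` (a
    stochastic mode samples them instead).  1-bp insertions copy
    protospacer position N17 with probability ``insertion_templating``.
    Shared synthesis artifacts (length-changing, away from the cut) are
    injected into both sample and control at ``background_rate``.

    Returns ``(sample_windows, control_windows, truth)`` with windows as
    dicts keyed by guide id and ``truth`` a DataFrame of the planted
    efficiency and class counts per library.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    if efficiencies is None:
        efficiencies = {gid: float(e) for gid, e in
                        zip(libraries, rng.uniform(5, 95, len(libraries)))}
    probs = np.array([p for _, _, p in CLASS_MIX])
    sample_w, control_w, rows = {}, {}, []
    for gid, site in libraries.items():
        ref = site.seq37
        depth = spec.read_depth
        n_bg = round(depth * spec.background_rate)
        n_edit_target = depth - n_bg
        e = efficiencies[gid]
        n_edited = round(n_edit_target * e / 100.0)
        if spec.stochastic_reads:
            counts = rng.multinomial(n_edited, probs)
        else:
            counts = _largest_remainder(probs, n_edited)
        windows: list[str] = []
        edited_set: set[str] = set()
        n17 = ref[10 + 16]
        other = "ACGT".replace(n17, "")[0]
        for (kind, size, _), cnt in zip(CLASS_MIX, counts):
            if cnt == 0:
                continue
            if kind == "del":
                w = _del_window(ref, size)
                windows.extend([w] * cnt)
                edited_set.add(w)
            elif size == 1:
                n_t = round(cnt * spec.insertion_templating)
                wt, wo = _ins_window(ref, 1, n17), _ins_window(ref, 1, other)
                windows.extend([wt] * n_t + [wo] * (cnt - n_t))
                edited_set.update((wt, wo))
            else:
                w = _ins_window(ref, size, n17)
                windows.extend([w] * cnt)
                edited_set.add(w)
        bg = _background_variant(ref, edited_set)
        n_unedited = depth - n_bg - len(windows)
        sample_w[gid] = [ref] * n_unedited + windows + [bg] * n_bg
        control_w[gid] = [ref] * (depth - n_bg) + [bg] * n_bg
        rows.append({
            "guide_id": gid, "depth": depth, "n_background": n_bg,
            "n_edited": len(windows), "n_unedited": n_unedited,
            "true_efficiency": 100.0 * len(windows) / (depth - n_bg),
            "n_ins1": int(counts[0]),
            "n_ins1_templated": round(int(counts[0]) * spec.insertion_templating),
            "background_window": bg, "n17": n17,
        })
    return sample_w, control_w, pd.DataFrame(rows)


def gen_reads(spec: GeneratorSpec, libraries: dict[str, SurrogateSite],
              efficiencies: dict[str, float] | None = None, seed: int | None = None):
    """Sample and control read sets with planted per-library edits.

    Reads are ``prefix + g + spacer + scaffold + window + linker + suffix``
    so they demultiplex by spacer+scaffold containment; the planted
    windows come from :func:`gen_windows`.  Returns
    ``(sample_reads, control_reads, truth)``.
    """
    sample_w, control_w, truth = gen_windows(spec, libraries, efficiencies, seed)
    sample, control = [], []
    for gid, site in libraries.items():
        key = "G" + site.protospacer + DEFAULT_SCAFFOLD
        sample.extend(f"AATTC{key}{w}{LINKER_SIGNATURE}ACGG" for w in sample_w[gid])
        control.extend(f"AATTC{key}{w}{LINKER_SIGNATURE}ACGG" for w in control_w[gid])
    return sample, control, truth


def surrogate_sites(spec: GeneratorSpec, n: int | None = None,
                    seed: int | None = None) -> dict[str, SurrogateSite]:
    """Random surrogate sites keyed by guide id (canonical NGG PAM)."""
    rng = np.random.default_rng((spec.seed if seed is None else seed) + 13)
    bases = np.array(list("ACGT"))
    out = {}
    for i in range(n or spec.n_guides):
        chars = bases[rng.integers(0, 4, size=37)]
        chars[31] = "G"
        chars[32] = "G"
        s = "".join(chars)
        out[f"g{i:05d}"] = SurrogateSite(s[:10], s[10:30], s[30:33], s[33:])
    return out
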