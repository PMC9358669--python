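"""Delta-mass / retention-time matching of protein complexes to ligands.

The central inference of a native-metabolomics screen: a protein-complex
feature at neutral mass P co-eluting with a metabolite feature L is
evidence that L (or n copies of it) is bound to the protein when

    |(P - apo_mass) - n * neutral(L)| <= mass_tol   and
    |rt_apex(P) - rt_apex(L)|        <= rt_tol.

Defaults follow the screening tolerances of a 25 kDa serine-protease
target: 4 Da mass tolerance (deconvolution accuracy at ~26 kDa) and
0.2 min retention-time tolerance on a shared 10-min gradient.  Matches are
many-to-many; ranking by absolute mass error and co-elution correlation is
left to the caller, and n >= 2 matches are flagged as possible nonspecific
binding.
"""

from __future__ import annotations

import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass

import pandas as pd

from nativemet.chem import PROTON_MASS
from nativemet.features import Feature, coelution_correlation

__all__ = ["ComplexMatch", "match", "apo_autodetect", "binding_ratio", "matches_to_table"]

DEFAULT_MASS_TOL = 4.0  # Da
DEFAULT_RT_TOL = 0.2  # minutes
DEFAULT_MAX_STOICHIOMETRY = 2

#: Adduct name -> (mass shift added to neutral M, charge).  Only [M+H]+ is
#: active by default; the others are configuration hooks.
ADDUCTS = {
    "[M+H]+": (PROTON_MASS, 1),
    "[M+2H]2+": (2 * PROTON_MASS, 2),
    "[M+Na]+": (22.9897692809 - 0.00054857990907, 1),
}


@dataclass
class ComplexMatch:
    """A (protein-complex feature, metabolite feature) pairing."""

    protein_feature_id: str
    metabolite_feature_id: str
    apo_mass: float
    delta_mass: float  # complex mass - apo mass
    ligand_neutral_mass: float
    mass_error: float  # delta_mass - n * ligand mass
    rt_diff: float
    coelution: float
    stoichiometry: int
    nonspecific_flag: bool = False


def neutral_ligand_mass(precursor_mz: float, adduct: str = "[M+H]+") -> float:
    """Neutral mass of a metabolite feature from its precursor m/z."""
    shift, z = ADDUCTS[adduct]
    return precursor_mz * z - shift


def match(
    protein_features: list[Feature],
    metabolite_features: list[Feature],
    apo_mass: float,
    mass_tol: float = DEFAULT_MASS_TOL,
    rt_tol: float = DEFAULT_RT_TOL,
    max_stoichiometry: int = DEFAULT_MAX_STOICHIOMETRY,
    adduct: str = "[M+H]+",
) -> list[ComplexMatch]:
    """Pair protein-complex features with metabolite features.

    For every protein feature P (persistent apo features excluded), ligand
    feature L, and stoichiometry n in [1, max_stoichiometry], a match is
    emitted iff the delta-mass and rt gates both hold.  The result equals
    brute-force enumeration over all (P, L, n) triples; the implementation
    prunes via a ligand-mass bisection but never drops a qualifying triple.
    Output is sorted by (protein rt apex, |mass_error|, ids).
    """
    if apo_mass <= 0:
        raise ValueError(f"apo_mass must be positive, got {apo_mass}")
    if mass_tol <= 0 or rt_tol <= 0:
        raise ValueError("tolerances must be positive")
    ligands = sorted(
        (f for f in metabolite_features),
        key=lambda f: neutral_ligand_mass(f.mass_value, adduct),
    )
    lig_masses = [neutral_ligand_mass(f.mass_value, adduct) for f in ligands]
    out: list[ComplexMatch] = []
    for p in protein_features:
        if p.persistent:
            continue
        delta = p.mass_value - apo_mass
        for n in range(1, max_stoichiometry + 1):
            target = delta / n
            lo = bisect_left(lig_masses, target - mass_tol / n)
            hi = bisect_right(lig_masses, target + mass_tol / n)
            for lf, lmass in zip(ligands[lo:hi], lig_masses[lo:hi]):
                if abs(delta - n * lmass) > mass_tol:
                    continue
                rt_diff = p.rt_apex - lf.rt_apex
                if abs(rt_diff) > rt_tol:
                    continue
                r = coelution_correlation(p, lf)
                out.append(
                    ComplexMatch(
                        protein_feature_id=p.id,
                        metabolite_feature_id=lf.id,
                        apo_mass=apo_mass,
                        delta_mass=delta,
                        ligand_neutral_mass=lmass,
                        mass_error=delta - n * lmass,
                        rt_diff=rt_diff,
                        coelution=0.0 if math.isnan(r) else r,
                        stoichiometry=n,
                        nonspecific_flag=n >= 2,
                    )
                )
    rt_by_id = {f.id: f.rt_apex for f in protein_features}
    out.sort(
        key=lambda m: (
            rt_by_id.get(m.protein_feature_id, 0.0),
            abs(m.mass_error),
            m.protein_feature_id,
            m.metabolite_feature_id,
            m.stoichiometry,
        )
    )
    return out


def apo_autodetect(
    protein_features: list[Feature],
    span_frac: float = 0.8,
    ambiguity_ratio: float = 1.1,
) -> float:
    """Infer the apo-protein mass from the protein feature table.

    The apo candidate is the highest-total-area feature whose rt extent
    covers at least ``span_frac`` of the observed rt span of the protein
    features.  If the runner-up candidate's area is within
    ``ambiguity_ratio`` of the best, the choice is ambiguous and an
    explicit apo mass must be supplied.
    """
    if not protein_features:
        raise ValueError("no protein features; cannot autodetect apo mass")
    lo = min(f.rt_start for f in protein_features)
    hi = max(f.rt_end for f in protein_features)
    span = hi - lo
    candidates = [
        f
        for f in protein_features
        if span <= 0 or (f.rt_end - f.rt_start) / span >= span_frac
    ]
    if not candidates:
        raise ValueError(
            "no protein feature spans enough of the run to be the apo protein; "
            "supply apo_mass explicitly"
        )
    candidates.sort(key=lambda f: (-f.area, f.mass_value))
    if len(candidates) > 1 and candidates[1].area * ambiguity_ratio >= candidates[0].area:
        raise ValueError(
            "ambiguous apo-protein detection: two candidates of comparable area "
            f"({candidates[0].mass_value:.1f} Da and {candidates[1].mass_value:.1f} Da); "
            "supply apo_mass explicitly"
        )
    return candidates[0].mass_value


def binding_ratio(p_complex: Feature, p_apo: Feature) -> float:
    """Complex / apo peak-area ratio over the complex's rt window.

    The apo trace is integrated over [rt_start, rt_end] of the complex
    feature.  A zero apo area yields +inf (flagged infinity marker).
    """
    import numpy as np

    if p_apo.trace_rt.size >= 2:
        lo, hi = p_complex.rt_start, p_complex.rt_end
        sel = (p_apo.trace_rt >= lo) & (p_apo.trace_rt <= hi)
        if sel.sum() >= 2:
            apo_area = float(np.trapezoid(p_apo.trace_intensity[sel], p_apo.trace_rt[sel]))
        else:
            apo_area = 0.0
    else:
        apo_area = p_apo.area
    if apo_area <= 0:
        return math.inf
    return p_complex.area / apo_area


def matches_to_table(matches: list[ComplexMatch]) -> pd.DataFrame:
    """Match table in the export column order."""
    return pd.DataFrame(
        {
            "protein_feature_id": [m.protein_feature_id for m in matches],
            "metabolite_feature_id": [m.metabolite_feature_id for m in matches],
            "apo_mass": [m.apo_mass for m in matches],
            "delta_mass": [m.delta_mass for m in matches],
            "ligand_mass": [m.ligand_neutral_mass for m in matches],
            "mass_error_da": [m.mass_error for m in matches],
            "rt_diff_min": [m.rt_diff for m in matches],
            "coelution_r": [m.coelution for m in matches],
            "stoichiometry": [m.stoichiometry for m in matches],
            "nonspecific_flag": [m.nonspecific_flag for m in matches],
        }
    )
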