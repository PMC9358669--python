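"""Delta-mass/RT matching against worked examples and a brute-force oracle."""

import math

import numpy as np
import pytest

from conftest import simple_feature
from nativemet.chem import PROTON_MASS
from nativemet.matching import (
    apo_autodetect,
    binding_ratio,
    match,
    neutral_ligand_mass,
)


def test_rivulariapeptolide_1185_worked_example():
    """Complex 26420 Da / ligand [M+H]+ 1186.6400 at 5.5 min, apo 25233:
    one match with delta 1187 and stoichiometry 1."""
    p = simple_feature("P1", 26420.0, 5.5, kind="protein")
    l = simple_feature("L1", 1186.6400, 5.5)
    out = match([p], [l], apo_mass=25233.0)
    assert len(out) == 1
    m = out[0]
    assert m.delta_mass == pytest.approx(1187.0, abs=0.01)
    assert m.stoichiometry == 1
    assert abs(m.mass_error) == pytest.approx(1.37, abs=0.05)
    assert abs(m.mass_error) <= 4.0
    assert m.coelution == pytest.approx(1.0, abs=1e-6)


def test_rivulariapeptolide_1155_worked_example():
    p = simple_feature("P1", 26385.0, 5.1, kind="protein")
    l = simple_feature("L1", 1156.5923, 5.1)
    out = match([p], [l], apo_mass=25233.0)
    assert len(out) == 1
    assert out[0].delta_mass == pytest.approx(1152.0, abs=0.01)


def test_two_molassamide_stoichiometry():
    """A complex 2 x 962.47 Da above apo matches molassamide with n = 2
    and is flagged as possibly nonspecific."""
    apo = 25232.6
    p = simple_feature("P1", 27157.6, 5.0, kind="protein")
    l = simple_feature("L1", 963.4822, 5.0)  # molassamide [M+H]+
    out = match([p], [l], apo_mass=apo)
    assert len(out) == 1
    m = out[0]
    assert m.stoichiometry == 2
    assert m.delta_mass == pytest.approx(1925.0, abs=0.01)
    assert m.nonspecific_flag


def test_rt_gate():
    p = simple_feature("P1", 26420.0, 5.8, kind="protein")
    l = simple_feature("L1", 1186.6400, 5.5)
    assert match([p], [l], apo_mass=25233.0, rt_tol=0.2) == []


def test_invalid_apo_mass_and_empty_inputs():
    with pytest.raises(ValueError):
        match([], [], apo_mass=-1.0)
    assert match([], [], apo_mass=25233.0) == []


def _random_tables(rng, n_p=8, n_l=10):
    apo = 25232.6
    prot = [
        simple_feature(f"P{i}", apo + rng.uniform(300, 2600), rng.uniform(3, 7),
                       kind="protein")
        for i in range(n_p)
    ]
    lig = [
        simple_feature(f"L{i}", rng.uniform(300, 1300), rng.uniform(3, 7))
        for i in range(n_l)
    ]
    return prot, lig, apo


def _brute_force(prot, lig, apo, mass_tol=4.0, rt_tol=0.2, max_n=2):
    """Independent O(n*m*k) enumeration of the match set."""
    hits = set()
    for p in prot:
        if p.persistent:
            continue
        for l in lig:
            for n in range(1, max_n + 1):
                lmass = l.mass_value - PROTON_MASS
                if (
                    abs((p.mass_value - apo) - n * lmass) <= mass_tol
                    and abs(p.rt_apex - l.rt_apex) <= rt_tol
                ):
                    hits.add((p.id, l.id, n))
    return hits


def test_equivalence_with_brute_force_oracle():
    """Match set identical to plain triple-loop enumeration on 100 random
    feature tables."""
    rng = np.random.default_rng(7)
    for _ in range(100):
        prot, lig, apo = _random_tables(rng)
        got = {
            (m.protein_feature_id, m.metabolite_feature_id, m.stoichiometry)
            for m in match(prot, lig, apo_mass=apo)
        }
        assert got == _brute_force(prot, lig, apo)


def test_tolerance_monotonicity():
    rng = np.random.default_rng(11)
    prot, lig, apo = _random_tables(rng, n_p=12, n_l=15)
    small = {
        (m.protein_feature_id, m.metabolite_feature_id, m.stoichiometry)
        for m in match(prot, lig, apo_mass=apo, mass_tol=2.0, rt_tol=0.1)
    }
    large = {
        (m.protein_feature_id, m.metabolite_feature_id, m.stoichiometry)
        for m in match(prot, lig, apo_mass=apo, mass_tol=6.0, rt_tol=0.3)
    }
    assert small.issubset(large)


def test_matches_respect_gates():
    rng = np.random.default_rng(13)
    prot, lig, apo = _random_tables(rng, n_p=15, n_l=20)
    for m in match(prot, lig, apo_mass=apo):
        assert abs(m.mass_error) <= 4.0
        assert abs(m.rt_diff) <= 0.2


def test_apo_autodetect_single_persistent():
    apo = simple_feature("P0", 25232.6, 5.0, kind="protein", persistent=True,
                         area=1e7)
    apo.rt_start, apo.rt_end = 0.0, 10.0
    peak = simple_feature("P1", 26420.0, 5.5, kind="protein", area=1e5)
    assert apo_autodetect([apo, peak]) == pytest.approx(25232.6)


def test_apo_autodetect_ambiguous():
    a = simple_feature("P0", 25232.6, 5.0, kind="protein", area=1e7)
    b = simple_feature("P1", 25600.0, 5.0, kind="protein", area=1e7)
    for f in (a, b):
        f.rt_start, f.rt_end = 0.0, 10.0
    with pytest.raises(ValueError, match="ambiguous"):
        apo_autodetect([a, b])


def test_apo_autodetect_single_feature():
    a = simple_feature("P0", 25232.6, 5.0, kind="protein", area=1e7)
    a.rt_start, a.rt_end = 0.0, 10.0
    assert apo_autodetect([a]) == pytest.approx(25232.6)


def test_binding_ratio():
    apo = simple_feature("P0", 25232.6, 5.5, kind="protein")
    # equal traces over the complex window -> ratio 1
    c1 = simple_feature("P1", 26420.0, 5.5, kind="protein")
    assert binding_ratio(c1, apo) == pytest.approx(1.0, rel=1e-6)
    # doubled complex trace -> ratio 2
    c2 = simple_feature("P2", 26420.0, 5.5, kind="protein")
    c2.trace_intensity = 2 * c2.trace_intensity
    c2.area = 2 * c2.area
    assert binding_ratio(c2, apo) == pytest.approx(2.0, rel=1e-6)
    # zero apo -> inf marker
    apo0 = simple_feature("P0", 25232.6, 5.5, kind="protein")
    apo0.trace_intensity = np.zeros_like(apo0.trace_intensity)
    apo0.area = 0.0
    assert math.isinf(binding_ratio(c1, apo0))


def test_neutral_ligand_mass():
    assert neutral_ligand_mass(1186.6400) == pytest.approx(1185.6327, abs=1e-3)
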