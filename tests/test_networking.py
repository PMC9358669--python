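"""Modified-cosine scoring and network assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import simple_feature
from nativemet.io import Spectrum
from nativemet.networking import build_network, modified_cosine


def _spec(mz, inten, prec, scan_id="s"):
    return Spectrum(scan_id, 5.0, 2, np.array(mz, dtype=float),
                    np.array(inten, dtype=float), precursor=(prec, 1))


def test_self_similarity_is_one():
    a = _spec([100, 150, 200, 250], [1, 4, 2, 8], 500.0)
    score, n = modified_cosine(a, a, min_matched=1)
    assert score == pytest.approx(1.0, abs=1e-9)
    assert n == 4


def test_disjoint_peaks_score_zero():
    a = _spec([100, 200], [1, 1], 500.0)
    b = _spec([130, 260], [1, 1], 500.0)
    score, n = modified_cosine(a, b, min_matched=1)
    assert score == 0.0
    assert n == 0


def test_shifted_channel_hand_example():
    """Two peaks pairing only through the precursor-shift channel give a
    perfect score (hand enumeration of all pairings)."""
    a = _spec([100.0, 200.0], [1.0, 1.0], 500.0)
    b = _spec([110.0, 210.0], [1.0, 1.0], 510.0)
    score, n = modified_cosine(a, b, frag_tol=0.02, min_matched=2)
    assert score == pytest.approx(1.0, abs=1e-9)
    assert n == 2


def test_min_matched_gates_score():
    a = _spec([100.0, 200.0], [1.0, 1.0], 500.0)
    score, n = modified_cosine(a, a, min_matched=6)
    assert score == 0.0
    assert n == 2


def test_empty_spectrum():
    a = _spec([100.0], [1.0], 500.0)
    b = Spectrum("e", 5.0, 2, np.array([]), np.array([]), precursor=(500.0, 1))
    assert modified_cosine(a, b, min_matched=1) == (0.0, 0)


@st.composite
def _random_spectrum(draw):
    n = draw(st.integers(min_value=1, max_value=6))
    mz = sorted(
        draw(
            st.lists(
                st.floats(min_value=50, max_value=900),
                min_size=n, max_size=n, unique=True,
            )
        )
    )
    inten = draw(
        st.lists(
            st.floats(min_value=0.1, max_value=100),
            min_size=n, max_size=n,
        )
    )
    prec = draw(st.floats(min_value=900, max_value=1200))
    return _spec(mz, inten, prec)


@given(a=_random_spectrum(), b=_random_spectrum())
@settings(derandomize=True, max_examples=100, deadline=None)
def test_symmetry_and_bounds(a, b):
    s_ab, n_ab = modified_cosine(a, b, min_matched=1)
    s_ba, n_ba = modified_cosine(b, a, min_matched=1)
    assert s_ab == s_ba
    assert n_ab == n_ba
    assert 0.0 <= s_ab <= 1.0 + 1e-9


@given(a=_random_spectrum(), b=_random_spectrum())
@settings(derandomize=True, max_examples=60, deadline=None)
def test_greedy_within_5pct_of_exact_assignment(a, b):
    """Greedy pairing score is within 5% of the optimal one-to-one
    assignment on small spectra."""
    greedy, _ = modified_cosine(a, b, min_matched=1)
    exact, _ = modified_cosine(a, b, min_matched=1, exact=True)
    assert greedy <= exact + 1e-9
    assert greedy >= 0.95 * exact - 1e-9


def test_against_matchms_oracle():
    """Cross-check the score against the matchms ModifiedCosine
    implementation (intensities pre-sqrt'd so both normalize alike)."""
    matchms = pytest.importorskip("matchms")
    from matchms.similarity import ModifiedCosine

    rng = np.random.default_rng(3)
    for _ in range(20):
        na, nb = rng.integers(3, 10, size=2)
        mza = np.sort(rng.uniform(50, 900, na))
        mzb = np.sort(rng.uniform(50, 900, nb))
        # plant some shared and shifted fragments, then re-sort b
        k = min(na, nb) // 2
        mzb[:k] = mza[:k]
        ia = rng.uniform(1, 100, na)
        ib = rng.uniform(1, 100, nb)
        order = np.argsort(mzb)
        mzb, ib = mzb[order], ib[order]
        pa, pb = 1000.0, 1037.5
        mine, _ = modified_cosine(
            _spec(mza, ia, pa), _spec(mzb, ib, pb), min_matched=1
        )
        sa = matchms.Spectrum(
            mz=mza, intensities=np.sqrt(ia),
            metadata={"precursor_mz": pa}, metadata_harmonization=False,
        )
        sb = matchms.Spectrum(
            mz=mzb, intensities=np.sqrt(ib),
            metadata={"precursor_mz": pb}, metadata_harmonization=False,
        )
        ref = ModifiedCosine(tolerance=0.02).pair(sa, sb)
        assert mine == pytest.approx(float(ref["score"]), abs=0.05)


def _family_features_and_spectra():
    base = [100.0, 160.0, 220.0, 310.0, 400.0, 480.0]
    feats, spectra = [], {}
    for i, shift in enumerate([0.0, 14.0, 28.0]):
        frag = [m + (shift if m > 250 else 0.0) for m in base]
        fid = f"M{i}"
        f = simple_feature(fid, 1000.0 + shift, 5.0 + 0.2 * i)
        f.msms_scan_ids = [f"scan{i}"]
        feats.append(f)
        spectra[f"scan{i}"] = _spec(frag, [1.0] * 6, 1000.0 + shift, scan_id=f"scan{i}")
    return feats, spectra


def test_network_analog_family_one_component():
    feats, spectra = _family_features_and_spectra()
    net = build_network(feats, spectra, score_threshold=0.7, min_matched=6)
    comps = net.components()
    assert sorted(len(c) for c in comps) == [3]
    assert len(net.edges_of_type("msms")) == 3


def test_decoy_excluded_from_family():
    feats, spectra = _family_features_and_spectra()
    decoy = simple_feature("D0", 700.0, 5.0)
    decoy.msms_scan_ids = ["scanD"]
    spectra["scanD"] = _spec([77.0, 133.0, 191.0, 255.0, 333.0, 417.0],
                             [1.0] * 6, 700.0, scan_id="scanD")
    net = build_network(feats + [decoy], spectra, score_threshold=0.7, min_matched=6)
    assert sorted(len(c) for c in net.components()) == [1, 3]


def test_threshold_monotonicity():
    feats, spectra = _family_features_and_spectra()
    low = build_network(feats, spectra, score_threshold=0.5, min_matched=6)
    high = build_network(feats, spectra, score_threshold=0.95, min_matched=6)
    low_edges = {frozenset(e[:2]) for e in low.edges_of_type("msms")}
    high_edges = {frozenset(e[:2]) for e in high.edges_of_type("msms")}
    assert high_edges.issubset(low_edges)


def test_top_k_cap_deterministic():
    """top_k=1 on a triangle of equal scores keeps each node's
    lowest-id partner only."""
    feats, spectra = _family_features_and_spectra()
    # make all three pairwise spectra identical -> equal scores
    for sid in spectra:
        spectra[sid] = _spec([100.0, 160.0, 220.0, 310.0, 400.0, 480.0],
                             [1.0] * 6, 1000.0, scan_id=sid)
    net = build_network(feats, spectra, score_threshold=0.5, min_matched=6, top_k=1)
    edges = sorted(tuple(sorted(e[:2])) for e in net.edges_of_type("msms"))
    assert edges == [("M0", "M1")]
    net2 = build_network(feats, spectra, score_threshold=0.5, min_matched=6, top_k=1)
    edges2 = sorted(tuple(sorted(e[:2])) for e in net2.edges_of_type("msms"))
    assert edges == edges2


def test_binding_edges_from_matches():
    from nativemet.matching import ComplexMatch

    feats, spectra = _family_features_and_spectra()
    matches = [
        ComplexMatch("P1", "M0", 25233.0, 1001.0, 999.0, 2.0, 0.0, 0.98, 1),
        ComplexMatch("P2", "M1", 25233.0, 1015.0, 1013.0, 2.0, 0.0, 0.97, 1),
    ]
    net = build_network(feats, spectra, matches=matches, apo_mass=25233.0)
    binding = net.edges_of_type("binding")
    assert len(binding) == 2
    assert all("protein" in (u, v) for u, v, _ in binding)
    assert net.graph.nodes["protein"]["kind"] == "protein"
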