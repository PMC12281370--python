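"""TCR-beta repertoire diversity statistics against brute-force oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from immunotriad.repertoire import (
    Clonotype,
    Repertoire,
    clonality,
    clone_size_bins,
    d50,
    metrics,
    overlap,
    read_airr,
    richness,
    shannon_entropy,
    track_top,
    write_airr,
)


def _rep(counts, prefix="C"):
    return Repertoire(
        [Clonotype(f"{prefix}{i}AAF", "TRBV9", int(c)) for i, c in enumerate(counts)]
    )


def _random_reps(n_reps, rng, max_clones=60, max_count=500):
    for _ in range(n_reps):
        n = int(rng.integers(1, max_clones))
        counts = rng.integers(1, max_count, size=n)
        yield _rep(counts)


# -- oracles ---------------------------------------------------------------

def _entropy_oracle(freqs):
    return -sum(f * math.log2(f) for f in freqs if f > 0)


def _d50_oracle(freqs):
    total, k = 0.0, 0
    for f in sorted(freqs, reverse=True):
        total += f
        k += 1
        if total >= 0.5:
            return k
    return k


def _bins_oracle(freqs):
    masses = {"small": 0.0, "medium": 0.0, "large": 0.0, "hyperexpanded": 0.0}
    for f in freqs:
        if f <= 1e-4:
            masses["small"] += f
        elif f <= 1e-3:
            masses["medium"] += f
        elif f <= 1e-2:
            masses["large"] += f
        else:
            masses["hyperexpanded"] += f
    return masses


# -- unit behaviour --------------------------------------------------------

def test_richness_and_dedup():
    rep = Repertoire(
        [
            Clonotype("CASSF", "TRBV9", 3),
            Clonotype("CASSF", "TRBV9", 2),  # same key: merged
            Clonotype("CASSF", "TRBV20", 1),  # same CDR3, different V: distinct
        ]
    )
    assert richness(rep) == 2
    assert rep.clonotypes[0].count == 5


@pytest.mark.parametrize("n", [2, 4, 16, 100])
def test_uniform_entropy_and_clonality(n):
    rep = _rep([7] * n)
    assert shannon_entropy(rep) == pytest.approx(math.log2(n), abs=1e-12)
    assert clonality(rep) == pytest.approx(0.0, abs=1e-12)


def test_monoclonal_extremes():
    rep = _rep([42])
    assert shannon_entropy(rep) == 0.0
    assert clonality(rep) == 1.0
    assert d50(rep) == 1


def test_entropy_and_clonality_derived_example():
    rep = _rep([70, 10, 10, 10])  # frequencies 0.7/0.1/0.1/0.1
    expected_h = _entropy_oracle([0.7, 0.1, 0.1, 0.1])
    assert expected_h == pytest.approx(1.3568, abs=5e-5)
    assert shannon_entropy(rep) == pytest.approx(expected_h, abs=1e-12)
    assert clonality(rep) == pytest.approx(1 - expected_h / 2.0, abs=1e-12)
    assert clonality(rep) == pytest.approx(0.3216, abs=5e-5)


@pytest.mark.parametrize("n", [2, 3, 7, 10, 11])
def test_d50_uniform(n):
    assert d50(_rep([5] * n)) == math.ceil(n / 2)


def test_d50_examples():
    assert d50(_rep([60, 20, 20])) == 1
    assert d50(_rep([30, 30, 20, 20])) == 2


def test_clone_size_bins_extremes_and_partition():
    assert clone_size_bins(_rep([100]))["hyperexpanded"] == pytest.approx(1.0)
    many = Repertoire([Clonotype(f"C{i}F", "TRBV9", 1) for i in range(100_000)])
    assert clone_size_bins(many)["small"] == pytest.approx(1.0)


def test_overlap_counts():
    a = _rep([5, 5, 5], prefix="A")
    b = _rep([2, 2], prefix="B")
    assert overlap(a, a) == (3, 1.0)
    assert overlap(a, b)[0] == 0
    shared = Repertoire(
        list(a.clonotypes) + [Clonotype(f"S{i}F", "TRBV9", 1) for i in range(7)]
    )
    other = Repertoire(
        list(b.clonotypes) + [Clonotype(f"S{i}F", "TRBV9", 2) for i in range(7)]
    )
    assert overlap(shared, other)[0] == 7
    assert overlap(shared, other) == overlap(other, shared)


def test_track_top_identity_and_absence():
    ref = _rep([50, 30, 20])
    mat = track_top(ref, [], k=3)
    assert np.allclose(mat.iloc[:, 0], sorted(ref.frequencies, reverse=True))
    other = _rep([10, 10], prefix="X")
    mat = track_top(ref, [other], k=2)
    assert (mat.iloc[:, 1] == 0).all()
    with pytest.raises(ValueError):
        track_top(ref, [], k=5)


def test_track_top_persistence_matrix():
    shared = [Clonotype("CSHAREDF", "TRBV9", c) for c in (50,)]
    ref = Repertoire(shared + [Clonotype("CREFF", "TRBV9", 50)], sample_id="ref")
    s1 = Repertoire([Clonotype("CSHAREDF", "TRBV9", 25), Clonotype("CXF", "TRBV9", 75)], "s1")
    s2 = Repertoire([Clonotype("CSHAREDF", "TRBV9", 10), Clonotype("CYF", "TRBV9", 90)], "s2")
    mat = track_top(ref, [s1, s2], k=2)
    row = mat.loc[("CSHAREDF", "TRBV9")]
    assert row.tolist() == pytest.approx([0.5, 0.25, 0.10])


def test_oracle_equivalence_on_random_repertoires():
    """Entropy, D50 and size-bin masses match term-by-term oracles on 1,000 draws."""
    rng = np.random.default_rng(42)
    for rep in _random_reps(1000, rng):
        freqs = rep.frequencies.tolist()
        assert shannon_entropy(rep) == pytest.approx(_entropy_oracle(freqs), abs=1e-9)
        assert d50(rep) == _d50_oracle(freqs)
        masses = clone_size_bins(rep)
        oracle = _bins_oracle(freqs)
        for k in masses:
            assert masses[k] == pytest.approx(oracle[k], abs=1e-9)
        assert sum(masses.values()) == pytest.approx(1.0, abs=1e-9)
        assert 0.0 <= clonality(rep) <= 1.0
        assert shannon_entropy(rep) <= math.log2(rep.n) + 1e-9


def test_expanding_largest_clone_never_decreases_clonality():
    rng = np.random.default_rng(7)
    for _ in range(50):
        counts = rng.integers(1, 100, size=int(rng.integers(2, 30)))
        base = clonality(_rep(counts))
        counts[int(np.argmax(counts))] *= 3
        assert clonality(_rep(counts)) >= base - 1e-12


def test_airr_roundtrip(tmp_path):
    rep = _rep([5, 3, 2])
    path = tmp_path / "sample.tsv"
    write_airr(rep, path)
    back = read_airr(path)
    assert back.keys() == rep.keys()
    assert np.allclose(back.frequencies, rep.frequencies)
    m = metrics(back)
    assert m["richness"] == 3


def test_synthetic_repertoire_frequencies_sum_to_one(cohort):
    for sid, grp in cohort.repertoire.groupby("sample_id"):
        rep = Repertoire.from_frame(grp, sample_id=str(sid))
        assert rep.frequencies.sum() == pytest.approx(1.0, abs=1e-9)
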