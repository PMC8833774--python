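"""Synthetic event generation, event-file IO and per-base statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from iodinedna import (
    DecayEvent,
    EnergyMixture,
    GeneratorConfig,
    InteractionRecord,
    OHHit,
    TrackDataset,
    accumulate_energy,
    energy_histogram,
    fraction_decayed,
    generate_events,
    per_base_statistics,
    read_scored_events,
    write_scored_events,
)


def zero_config(n_bases=40, seed=0):
    z = np.zeros(n_bases)
    return GeneratorConfig(n_bases=n_bases, interaction_rate=z, oh_rate=z, seed=seed)


# --------------------------------------------------------------------------
# generation


def test_zero_rates_give_empty_events():
    ds = generate_events(zero_config(), 100)
    assert ds.n_decays == 100
    assert len(ds.interactions) == 0 and len(ds.oh_hits) == 0
    assert ds.energy_matrix().sum() == 0


def test_degenerate_single_interaction_at_iodine_base():
    """A fixed-count, zero-width-peak world puts exactly one 32 eV record at
    (strand 0, base 0) in every event."""
    rate = np.zeros((2, 10))
    rate[0, 0] = 1.0
    cfg = GeneratorConfig(
        n_bases=10,
        interaction_rate=rate,
        oh_rate=np.zeros(10),
        energy_mixture=EnergyMixture(peaks=((32.0, 0.0),), weights=(0.0, 1.0)),
        seed=3,
        count_law="fixed",
    )
    ds = generate_events(cfg, 500)
    assert len(ds.interactions) == 500
    assert (ds.interactions["strand"] == 0).all()
    assert (ds.interactions["base"] == 0).all()
    assert np.allclose(ds.interactions["energy_eV"], 32.0)


def test_mean_energy_matches_compound_poisson_law():
    """LLN oracle: with Poisson(lambda) counts at one base and i.i.d. mixture
    energies, the mean deposit per decay is lambda*mu within 3 SEs, where mu
    and the compound-Poisson variance are computed analytically here."""
    lam = 0.05
    rate = np.zeros(40)
    rate[10] = lam
    mix = EnergyMixture()  # (0.25,12] continuum 0.6; peaks 17 (0.15), 32 (0.25)
    cfg = GeneratorConfig(interaction_rate=rate, oh_rate=np.zeros(40), energy_mixture=mix, seed=11)
    n = 200_000
    ds = generate_events(cfg, n)

    lo, hi = 0.25, 12.0
    mu = 0.6 * (lo + hi) / 2 + 0.15 * 17.0 + 0.25 * 32.0
    m2 = 0.6 * (lo**2 + lo * hi + hi**2) / 3 + 0.15 * (17.0**2 + 0.3**2) + 0.25 * (
        32.0**2 + 0.3**2
    )
    se = math.sqrt(lam * m2 / n)  # Var of compound Poisson per decay = lam*E[X^2]

    observed = ds.energy_matrix()[:, 0, 10].mean()
    assert abs(observed - lam * mu) < 3 * se


def test_frac_nonzero_matches_poisson_zero_probability(small_dataset, default_config):
    """P(deposit > 0) at each base = 1 - exp(-lambda) within 3 binomial SEs."""
    stats = per_base_statistics(small_dataset)
    lam = default_config.interaction_rate
    expected = 1.0 - np.exp(-lam)
    se = np.sqrt(expected * (1 - expected) / small_dataset.n_decays)
    z = np.abs(stats.frac_nonzero - expected) / se
    # 80 simultaneous sites: bound the worst z rather than each at 3 sigma
    assert z.max() < 4.0
    assert np.median(z) < 1.5


def test_generation_is_deterministic(default_config):
    a = generate_events(default_config, 300)
    b = generate_events(default_config, 300)
    pd.testing.assert_frame_equal(a.interactions, b.interactions)
    pd.testing.assert_frame_equal(a.oh_hits, b.oh_hits)


@pytest.mark.parametrize(
    "build",
    [
        lambda: GeneratorConfig(interaction_rate=-np.ones(40)),
        lambda: GeneratorConfig(oh_rate=np.full(40, np.nan)),
        lambda: EnergyMixture(weights=(0.5, 0.2, 0.2)),  # sum != 1
        lambda: EnergyMixture(continuum=(5.0, 1.0)),
        lambda: GeneratorConfig(count_law="negative-binomial"),
    ],
)
def test_invalid_generator_config_rejected(build):
    with pytest.raises(ValueError):
        build()


def test_generate_requires_events():
    with pytest.raises(ValueError):
        generate_events(zero_config(), 0)


# --------------------------------------------------------------------------
# file IO


def test_single_row_file_roundtrip(tmp_path):
    p = tmp_path / "one.csv"
    p.write_text(
        "event_id,record_type,strand,base,energy_eV\n0,EDEP,0,3,17.5\n", encoding="utf-8"
    )
    ds = read_scored_events(p)
    assert ds.n_decays == 1
    assert len(ds.interactions) == 1
    ev = ds.event(0)
    assert ev.interactions == (InteractionRecord(0, 3, 17.5),)


def test_write_read_roundtrip_preserves_statistics(tmp_path, small_dataset):
    p = tmp_path / "events.csv"
    write_scored_events(small_dataset, p)
    back = read_scored_events(p)
    assert back.n_decays == small_dataset.n_decays
    assert back.n_bases == small_dataset.n_bases
    assert back.label == small_dataset.label
    a, b = per_base_statistics(small_dataset), per_base_statistics(back)
    # writer sorts rows, so site sums re-accumulate in a different order:
    # identical to machine precision, not bit-for-bit
    np.testing.assert_allclose(a.mean_energy_per_decay, b.mean_energy_per_decay, rtol=1e-12)
    np.testing.assert_array_equal(a.frac_nonzero, b.frac_nonzero)
    np.testing.assert_array_equal(a.mean_oh_hits, b.mean_oh_hits)


def test_row_order_is_immaterial(tmp_path, small_dataset):
    p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
    write_scored_events(small_dataset, p1)
    lines = p1.read_text().splitlines()
    head, rows = lines[:4], lines[4:]
    p2.write_text("\n".join(head + rows[::-1]) + "\n", encoding="utf-8")
    a, b = read_scored_events(p1), read_scored_events(p2)
    np.testing.assert_allclose(a.energy_matrix(), b.energy_matrix(), rtol=1e-12)
    np.testing.assert_array_equal(a.oh_count_matrix(), b.oh_count_matrix())


@pytest.mark.parametrize(
    "row,msg",
    [
        ("0,EDEP,0,40,5.0", "base index"),
        ("0,EDEP,0,3,-2.0", "energy"),
        ("0,XRAY,0,3,5.0", "record_type"),
        ("0,EDEP,2,3,5.0", "strand"),
    ],
)
def test_malformed_rows_name_the_line(tmp_path, row, msg):
    p = tmp_path / "bad.csv"
    p.write_text(
        "# n_decays: 2\n# n_bases: 40\nevent_id,record_type,strand,base,energy_eV\n"
        f"0,EDEP,0,1,5.0\n{row}\n",
        encoding="utf-8",
    )
    with pytest.raises(ValueError, match="line 5"):
        read_scored_events(p)


def test_schema_mapping_renames_columns(tmp_path):
    p = tmp_path / "alt.csv"
    p.write_text("evt,kind,str,bp,E\n0,EDEP,1,2,9.5\n", encoding="utf-8")
    ds = read_scored_events(
        p,
        schema={
            "event_id": "evt",
            "record_type": "kind",
            "strand": "str",
            "base": "bp",
            "energy_eV": "E",
        },
    )
    assert ds.energy_matrix()[0, 1, 2] == 9.5


# --------------------------------------------------------------------------
# accumulation and statistics


def test_accumulate_energy_adds_per_site():
    ev = DecayEvent(
        0, (InteractionRecord(0, 5, 10.0), InteractionRecord(0, 5, 12.0)), ()
    )
    acc = accumulate_energy(ev, 40)
    assert acc[0, 5] == 22.0
    assert acc.sum() == 22.0


def test_accumulate_energy_empty_event_is_zero():
    assert accumulate_energy(DecayEvent(0), 40).sum() == 0.0


def test_accumulate_energy_matches_bruteforce(rng):
    """Oracle: independent dict-based group-by-sum over the raw records."""
    for _ in range(50):
        n_rec = rng.integers(0, 15)
        recs = tuple(
            InteractionRecord(int(rng.integers(2)), int(rng.integers(8)), float(rng.uniform(0.1, 40)))
            for _ in range(n_rec)
        )
        ev = DecayEvent(0, recs, ())
        acc = accumulate_energy(ev, 8)
        expected: dict[tuple[int, int], float] = {}
        for r in recs:
            expected[(r.strand, r.base)] = expected.get((r.strand, r.base), 0.0) + r.energy
        for (s, b), e in expected.items():
            assert acc[s, b] == pytest.approx(e)
        assert acc.sum() == pytest.approx(sum(r.energy for r in recs))


def test_dataset_energy_matrix_matches_per_event_accumulation(small_dataset):
    """Conservation: the columnar accumulation equals per-event sums."""
    E = small_dataset.energy_matrix()
    assert E.sum() == pytest.approx(small_dataset.interactions["energy_eV"].sum())
    for eid in (0, 1, 2, 57):
        np.testing.assert_allclose(
            E[eid], accumulate_energy(small_dataset.event(eid), small_dataset.n_bases)
        )


def test_per_base_statistics_trivial_cases():
    events = [
        DecayEvent(0, (InteractionRecord(0, 10, 22.0),), (OHHit(1, 4),)),
        DecayEvent(1),
    ]
    stats = per_base_statistics(TrackDataset.from_events(events, n_bases=40))
    assert stats.mean_energy_per_decay[0, 10] == 11.0
    assert stats.frac_nonzero[0, 10] == 0.5
    assert stats.mean_oh_hits[1, 4] == 0.5

    empty = per_base_statistics(TrackDataset.from_events([DecayEvent(0), DecayEvent(1)]))
    assert empty.mean_energy_per_decay.sum() == 0
    assert empty.frac_nonzero.sum() == 0


# --------------------------------------------------------------------------
# histograms


def test_histogram_single_interaction():
    ds = TrackDataset.from_events([DecayEvent(0, (InteractionRecord(0, 3, 32.0),), ())])
    h = energy_histogram(ds, "per-interaction", bin_width=1.0)
    assert h.counts.sum() == 1
    k = np.searchsorted(h.edges, 32.0, side="right") - 1
    assert h.edges[k] == 32.0 and h.counts[k] == 1


def test_histogram_empty_dataset():
    ds = TrackDataset.from_events([DecayEvent(0)])
    h = energy_histogram(ds, "per-interaction")
    assert h.counts.sum() == 0


def test_histogram_conserves_counts_and_flags_exclusions(small_dataset):
    h = energy_histogram(small_dataset, "per-interaction", bin_width=0.5, exclude_below=5.0)
    assert h.counts.sum() + h.n_excluded == len(small_dataset.interactions)
    assert h.n_excluded == int((small_dataset.interactions["energy_eV"] < 5.0).sum())

    hb = energy_histogram(small_dataset, "per-decay-per-base", base=10, strand=0)
    nonzero = int((small_dataset.energy_matrix()[:, 0, 10] > 0).sum())
    assert hb.counts.sum() == nonzero


def test_histogram_rejects_bad_arguments(small_dataset):
    with pytest.raises(ValueError):
        energy_histogram(small_dataset, "per-decade")
    with pytest.raises(ValueError):
        energy_histogram(small_dataset, "per-interaction", bin_width=0)
    with pytest.raises(ValueError):
        energy_histogram(small_dataset, "per-decay-per-base")  # no base


def test_interaction_histogram_matches_mixture(medium_dataset):
    """Sampling oracle: coarse three-way split of interaction energies
    (continuum / 17-peak / 32-peak regions) follows the mixture weights by a
    chi-square goodness-of-fit test."""
    e = medium_dataset.interactions["energy_eV"].to_numpy()
    observed = np.array([(e <= 14.5).sum(), ((e > 14.5) & (e <= 24.5)).sum(), (e > 24.5).sum()])
    expected = np.array([0.60, 0.15, 0.25]) * e.size
    chi2, p = sps.chisquare(observed, expected)
    assert p > 1e-3


# --------------------------------------------------------------------------
# decay physics


def test_twenty_days_decays_about_a_fifth():
    assert fraction_decayed(20.0) == pytest.approx(0.2081, abs=5e-4)
    assert fraction_decayed(0.0) == 0.0
    with pytest.raises(ValueError):
        fraction_decayed(-1.0)
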