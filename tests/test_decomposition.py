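"""Rate tables, percent contrasts, counterfactual decomposition, permutation test."""

import numpy as np
import pandas as pd
import pytest

import trajmix as tm
from trajmix.decomposition import (cohort_gap, decompose, percent_excess,
                                   permutation_test, rate_table)
from trajmix.simulate import CohortSpec, GenerativeSpec
from trajmix.basis import TrajectorySpec

from conftest import make_random_panel


def _flat_panel(totals_by_person, cohort="y", window=(17, 24)):
    """Panel where each person's counts spread their total over the window."""
    rows = []
    lo, hi = window
    span = hi - lo + 1
    for pid, total in totals_by_person.items():
        base, extra = divmod(total, span)
        for k, age in enumerate(range(lo, hi + 1)):
            rows.append({"person_id": pid, "cohort": cohort, "age": age,
                         "count": base + (1 if k < extra else 0)})
    return tm.Panel(pd.DataFrame(rows))


def test_rate_table_cell_mean():
    panel = _flat_panel({"A": 6, "B": 10})
    table = rate_table(panel, {"A": 0, "B": 0}, (17, 24))
    assert table.cell(0, "y") == pytest.approx(8.0)
    assert table.table.loc[(0, "y"), "n_persons"] == 2


def test_rate_table_empty_cell_absent():
    panel = _flat_panel({"A": 4})
    table = rate_table(panel, {"A": 1}, (17, 24))
    assert (0, "y") not in table.table.index
    assert (1, "y") in table.table.index


def test_rate_table_partial_coverage():
    df = pd.DataFrame({"person_id": "A", "age": range(18, 25), "count": 1})
    short = tm.Panel(df)  # observed 18-24 only
    full = _flat_panel({"B": 8})
    both = tm.Panel(pd.concat([short.data, full.data], ignore_index=True))
    table = rate_table(both, {"A": 0, "B": 0}, (17, 24))
    assert table.n_excluded == 1
    assert table.table.loc[(0, "y"), "n_persons"] == 1
    with pytest.raises(ValueError, match="coverage"):
        rate_table(both, {"A": 0, "B": 0}, (17, 24), on_partial="error")


def test_rate_table_by_offense_and_drug_gap_direction():
    """Older high-group drug inclusion >> younger's shows up in the drug cell."""
    tspec = TrajectorySpec(degree=0)
    mix = tm.MixtureModel(specs=(tspec,), beta=(np.array([np.log(1.2)]),),
                          theta=np.zeros((0, 1)), age_range=(17.0, 24.0))
    spec = GenerativeSpec(
        mixture=mix,
        cohorts=(CohortSpec("y", 0.5, (17, 24)), CohortSpec("o", 0.5, (17, 24))),
        older_labels=("o",),
        charge_mix={(0, "younger"): {"drugs": 0.15, "violence": 0.2, "property": 0.2, "other": 0.5},
                    (0, "older"): {"drugs": 0.4, "violence": 0.2, "property": 0.2, "other": 0.5}},
        seed=0)
    panel, _, labels = tm.simulate_panel(spec, 1500, seed=2)
    table = rate_table(panel, labels, (17, 24), by_offense=True)
    assert table.cell(0, "o", "rate_drugs") > table.cell(0, "y", "rate_drugs")
    # category cells need not sum to the total cell
    assert "rate_other" in table.table.columns


def test_percent_excess_values():
    assert percent_excess(10.88, 8.07) == pytest.approx(34.8, abs=0.05)
    assert percent_excess(2.0, 2.0) == 0.0
    assert percent_excess(3.0, 2.0) == pytest.approx(50.0)
    with pytest.raises(ValueError):
        percent_excess(1.0, 0.0)


def test_cohort_gap_values():
    assert cohort_gap(0.614, 1.156) == pytest.approx(0.542, abs=1e-12)
    assert cohort_gap(1.0, 1.0) == 0.0
    assert cohort_gap(2.0, 3.0) == -cohort_gap(3.0, 2.0)


def test_decompose_identity_when_equal():
    d = decompose([0.6, 0.4], [1.0, 3.0], [0.6, 0.4], [1.0, 3.0])
    assert d.actual_young == d.actual_old == d.rate_swap == d.composition_swap
    assert d.gap == 0.0
    assert d.pct_rate_swap == pytest.approx(0.0)


def test_decompose_two_group_hand_example():
    d = decompose([0.5, 0.5], [0.0, 2.0], [0.8, 0.2], [0.0, 4.0])
    assert d.actual_young == pytest.approx(1.0)
    assert d.actual_old == pytest.approx(0.8)
    assert d.composition_swap == pytest.approx(0.4)
    assert d.rate_swap == pytest.approx(2.0)
    assert d.targeted_swap[1] == pytest.approx(0.5 * 0 + 0.5 * 4)


def test_decompose_matches_published_arithmetic():
    """Printed shares x printed rates reproduce the published counterfactual."""
    d = decompose([0.88, 0.086, 0.037], [0.10, 2.52, 8.07],
                  [0.74, 0.21, 0.049], [0.16, 2.44, 10.88])
    assert d.composition_swap == pytest.approx(0.995, rel=0.015)
    assert d.actual_young == pytest.approx(0.614, abs=0.015)
    assert d.actual_old == pytest.approx(1.156, abs=0.02)


def test_decompose_share_normalization_enforced():
    with pytest.raises(ValueError, match="sum"):
        decompose([0.5, 0.3], [1, 1], [0.5, 0.5], [1, 1])


def test_decompose_order_invariance():
    perm = [2, 0, 1]
    sy, ry = np.array([0.2, 0.3, 0.5]), np.array([1.0, 2.0, 3.0])
    so, ro = np.array([0.4, 0.4, 0.2]), np.array([0.5, 2.5, 4.0])
    a = decompose(sy, ry, so, ro)
    b = decompose(sy[perm], ry[perm], so[perm], ro[perm])
    assert a.actual_young == pytest.approx(b.actual_young, abs=1e-12)
    assert a.rate_swap == pytest.approx(b.rate_swap, abs=1e-12)
    assert a.composition_swap == pytest.approx(b.composition_swap, abs=1e-12)


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_additive_identity_on_random_panels(seed):
    """Share-weighted within-group means equal the pooled cohort mean exactly."""
    rng = np.random.default_rng(seed)
    panel = make_random_panel(rng, n_persons=30)
    persons = panel.persons
    assign = pd.Series(rng.integers(0, 3, len(persons)), index=persons)
    window = panel.age_range
    totals = panel.person_totals(window=window)
    coh = panel.cohorts
    for c in coh.unique():
        members = coh.index[coh == c]
        g = assign.reindex(members)
        shares = np.array([(g == j).mean() for j in range(3)])
        rates = np.array([totals[g[g == j].index].mean() if (g == j).any() else 0.0
                          for j in range(3)])
        pooled = totals.reindex(members).mean()
        assert shares @ rates == pytest.approx(pooled, abs=1e-12)


def test_permutation_test_null_case():
    """Identical count multisets across cohorts: p is (near) 1."""
    young = _flat_panel({f"y{i}": i % 4 for i in range(12)}, cohort="y")
    old = _flat_panel({f"o{i}": i % 4 for i in range(12)}, cohort="o")
    panel = tm.Panel(pd.concat([young.data, old.data], ignore_index=True))
    assign = pd.Series(0, index=panel.persons)
    p = permutation_test(panel, assign, 0, (17, 24), n_perm=499, seed=1)
    assert p > 0.99


def test_permutation_test_separated_distributions():
    """All-zero vs all-five cohorts (n=20 each): p at the attainable floor."""
    young = _flat_panel({f"y{i}": 0 for i in range(20)}, cohort="y")
    old = _flat_panel({f"o{i}": 5 for i in range(20)}, cohort="o")
    panel = tm.Panel(pd.concat([young.data, old.data], ignore_index=True))
    assign = pd.Series(0, index=panel.persons)
    p = permutation_test(panel, assign, 0, (17, 24), n_perm=999, seed=1)
    assert p <= 0.01


def test_permutation_test_seed_stability():
    rng = np.random.default_rng(7)
    panel = make_random_panel(rng, n_persons=40)
    assign = pd.Series(0, index=panel.persons)
    window = panel.age_range
    p1 = permutation_test(panel, assign, 0, window, n_perm=10_000, seed=1)
    p2 = permutation_test(panel, assign, 0, window, n_perm=10_000, seed=2)
    mc_se = np.sqrt(max(p1 * (1 - p1), 0.01) / 10_000)
    assert abs(p1 - p2) < 5 * mc_se + 1e-3


def test_permutation_test_requires_both_cohorts():
    panel = _flat_panel({"A": 1, "B": 2}, cohort="y")
    with pytest.raises(ValueError, match="two cohorts"):
        permutation_test(panel, pd.Series(0, index=panel.persons), 0, (17, 24))
    with pytest.raises(ValueError, match="empty"):
        permutation_test(panel, pd.Series(1, index=panel.persons), 0, (17, 24))
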