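import itertools

import numpy as np
import pandas as pd
import pytest

from refstab.stability_deltact import deltact_stability
from refstab.stability_genorm import (
    QuantityMatrix,
    m_values,
    pairwise_variation_matrix,
    relative_quantities,
    stepwise_ranking,
)
from .conftest import make_dataset


def brute_force_m(q: pd.DataFrame) -> pd.Series:
    """Definitional oracle: M_g = mean over k!=g of popSD(log2(Q_g/Q_k))."""
    genes = list(q.index)
    out = {}
    for g in genes:
        sds = []
        for k in genes:
            if k == g:
                continue
            a = [np.log2(q.loc[g, s] / q.loc[k, s]) for s in q.columns]
            m = sum(a) / len(a)
            sds.append((sum((x - m) ** 2 for x in a) / len(a)) ** 0.5)
        out[g] = sum(sds) / len(sds)
    return pd.Series(out)


def brute_force_stepwise(q: pd.DataFrame):
    """Exhaustive oracle: recompute M from the definition at every round."""
    rounds, exclusion = [], []
    remaining = q.copy()
    while remaining.shape[0] > 2:
        m = brute_force_m(remaining)
        rounds.append(m)
        worst = max(sorted(m.index), key=lambda g: (m[g], g))
        exclusion.append(worst)
        remaining = remaining.drop(index=worst)
    rounds.append(brute_force_m(remaining))
    return rounds, exclusion, frozenset(remaining.index)


def _random_quantities(seed, G=5, S=8):
    rng = np.random.default_rng(seed)
    q = 2.0 ** rng.uniform(-8, 0, size=(G, S))
    q = q / q.max(axis=1, keepdims=True)
    return pd.DataFrame(q, index=[f"g{i}" for i in range(G)],
                        columns=[f"s{j}" for j in range(S)])


def test_relative_quantities_powers_of_two():
    ds = make_dataset([[20.0, 21.0, 23.0]], ["g"])
    q = relative_quantities(ds, default_e=2.0)
    assert np.allclose(q.q.loc["g"], [1.0, 0.5, 0.125])


def test_relative_quantities_literature_efficiency():
    ds = make_dataset([[20.0, 21.0]], ["60s"], efficiencies={"60s": 1.910})
    q = relative_quantities(ds)
    assert q.q.loc["60s"].iloc[0] == 1.0
    assert q.q.loc["60s"].iloc[1] == pytest.approx(1 / 1.910, abs=1e-12)


def test_relative_quantities_all_equal_cts():
    ds = make_dataset([[22.0, 22.0, 22.0], [25.0, 25.0, 25.0]], ["a", "b"])
    q = relative_quantities(ds, default_e=2.0)
    assert (q.q.to_numpy() == 1.0).all()


def test_relative_quantities_rejects_missing_and_bad_e():
    ds = make_dataset([[20.0, np.nan]], ["g"])
    with pytest.raises(ValueError, match="missing CT"):
        relative_quantities(ds, default_e=2.0)
    ds2 = make_dataset([[20.0, 21.0]], ["g"])
    with pytest.raises(ValueError, match="outside"):
        relative_quantities(ds2, default_e=2.5)


def test_m_zero_for_proportional_quantities():
    base = np.array([1.0, 0.5, 0.25, 0.125])
    q = pd.DataFrame([base, base * 0.7, base * 0.2], index=list("abc"))
    m = m_values(q)
    assert np.allclose(m.to_numpy(), 0.0, atol=1e-12)


def test_m_matches_brute_force_oracle():
    q = _random_quantities(21, G=4, S=6)
    assert np.allclose(m_values(q).to_numpy(), brute_force_m(q).to_numpy(), atol=1e-12)


def test_m_invariant_to_sample_and_gene_rescaling():
    q = _random_quantities(3)
    m0 = m_values(q)
    rng = np.random.default_rng(4)
    q2 = q * rng.uniform(0.1, 10, size=(1, q.shape[1]))  # per-sample scaling
    q2.iloc[2] *= 5.0  # per-gene constant
    assert np.allclose(m0.to_numpy(), m_values(q2).to_numpy(), atol=1e-9)


def test_equivalence_with_deltact_at_e2():
    rng = np.random.default_rng(17)
    ds = make_dataset(rng.uniform(15, 32, (6, 10)), [f"g{i}" for i in range(6)])
    q = relative_quantities(ds, default_e=2.0)
    v = pairwise_variation_matrix(q)
    d = deltact_stability(ds)
    assert np.allclose(v.to_numpy(), d.pair_sd.to_numpy(), atol=1e-9)
    assert np.allclose(m_values(q).to_numpy(), d.mean_sd.to_numpy(), atol=1e-9)


def test_stepwise_excludes_the_noisy_gene():
    rng = np.random.default_rng(9)
    base = 2.0 ** rng.uniform(-6, 0, size=8)
    q = pd.DataFrame(
        [base, base * 0.5, base * 0.1, 2.0 ** rng.uniform(-6, 0, size=8)],
        index=list("ABCD"),
    )
    q = q.div(q.max(axis=1), axis=0)
    trace = stepwise_ranking(QuantityMatrix(q, {g: 2.0 for g in "ABCD"}))
    assert trace.exclusion_order[0] == "D"
    assert trace.final_pair <= {"A", "B", "C"}


@pytest.mark.parametrize("seed", range(10))
def test_stepwise_matches_exhaustive_oracle(seed):
    q = _random_quantities(seed)
    trace = stepwise_ranking(QuantityMatrix(q, {g: 2.0 for g in q.index}))
    rounds, exclusion, final = brute_force_stepwise(q)
    assert trace.exclusion_order == exclusion
    assert trace.final_pair == final
    for got, exp in zip(trace.rounds, rounds):
        assert set(got.index) == set(exp.index)
        assert np.allclose(got.loc[exp.index].to_numpy(), exp.to_numpy(), atol=1e-9)


def test_nf_is_gene_order_invariant():
    q = _random_quantities(33)
    trace = stepwise_ranking(QuantityMatrix(q, {g: 2.0 for g in q.index}))
    top3 = trace.ranking[:3]
    for perm in itertools.permutations(top3):
        nf = 2.0 ** np.log2(q.loc[list(perm)].to_numpy()).mean(axis=0)
        assert np.allclose(nf, trace.nf[3].to_numpy(), atol=1e-12)


def test_v_ratios_nonnegative_and_complete():
    q = _random_quantities(2, G=6, S=12)
    trace = stepwise_ranking(QuantityMatrix(q, {g: 2.0 for g in q.index}))
    assert sorted(trace.v_ratios) == [2, 3, 4, 5]
    assert all(v >= 0 for v in trace.v_ratios.values())


def test_stepwise_needs_three_genes():
    q = _random_quantities(1, G=2)
    with pytest.raises(ValueError):
        stepwise_ranking(QuantityMatrix(q, {g: 2.0 for g in q.index}))
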