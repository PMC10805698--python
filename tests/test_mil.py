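"""Bag model contracts: permutation invariance, aggregation, heads, I/O."""

import numpy as np
import pytest

from mutmil.autodiff import Tensor
from mutmil.mil import (
    Bag,
    CategoricalConcept,
    IdentityConcept,
    MILClassifier,
    ModelConfig,
    SequenceConceptSpec,
    msi_reference_config,
)


def random_bags(n_bags=12, n_codes=10, rng=None, n_classes=2):
    rng = rng or np.random.default_rng(0)
    bags = []
    for i in range(n_bags):
        n = int(rng.integers(3, 12))
        codes = rng.integers(0, n_codes, size=n)
        bags.append(
            Bag(
                sample_id=f"b{i}",
                instances={"code": codes, "onehot": np.eye(n_codes)[codes]},
                label=int(rng.integers(0, n_classes)),
            )
        )
    return bags


def shuffle_bag(bag, rng):
    perm = rng.permutation(bag.n_instances)
    return Bag(
        sample_id=bag.sample_id,
        instances={k: v[perm] for k, v in bag.instances.items()},
        label=bag.label,
    )


@pytest.mark.parametrize("aggregation", ["mean", "sum", "dynamic"])
def test_predictions_invariant_to_instance_order(aggregation):
    rng = np.random.default_rng(5)
    bags = random_bags(rng=rng)
    cfg = ModelConfig(aggregation=aggregation, instance_dim=8, hidden=(8,), seed=1)
    m = MILClassifier(bags, [CategoricalConcept("code", 10, 4)], config=cfg)
    p1 = m.predict_proba(bags)
    shuffled = [shuffle_bag(b, rng) for b in bags]
    p2 = m.predict_proba(shuffled)
    np.testing.assert_allclose(p1, p2, atol=1e-6)


def test_probabilities_sum_to_one_multiclass():
    bags = random_bags(n_classes=3)
    m = MILClassifier(bags, [CategoricalConcept("code", 10, 4)], n_classes=3)
    p = m.predict_proba(bags)
    np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
    assert p.shape == (len(bags), 3)


def test_zeroed_output_layer_gives_uniform_probabilities():
    bags = random_bags(n_classes=3)
    m = MILClassifier(bags, [CategoricalConcept("code", 10, 4)], n_classes=3)
    m.out.W.data[...] = 0.0
    m.out.b.data[...] = 0.0
    p = m.predict_proba(bags)
    np.testing.assert_allclose(p, 1.0 / 3.0, atol=1e-12)


def test_identical_instances_mean_aggregation_returns_instance_features():
    # a bag of identical instances under mean aggregation must aggregate to
    # that instance's feature vector per head, for any attention values
    code = np.array([3, 3, 3, 3])
    bag = Bag("b", {"code": code, "onehot": np.eye(10)[code]}, label=0)
    ref = Bag("r", {"code": code[:1], "onehot": np.eye(10)[code[:1]]}, label=0)
    m = MILClassifier(
        [bag, ref],
        [CategoricalConcept("code", 10, 4)],
        config=ModelConfig(aggregation="mean", instance_dim=6, seed=2),
        n_classes=2,
    )
    p = m.predict_proba([bag, ref])
    np.testing.assert_allclose(p[0], p[1], atol=1e-9)


def test_identical_instances_have_identical_attention_rows():
    code = np.array([3, 3, 3])
    bag = Bag("b", {"code": code, "onehot": np.eye(10)[code]}, label=0)
    bags = [bag] + random_bags(n_bags=3)
    m = MILClassifier(bags, [CategoricalConcept("code", 10, 4)])
    a = m.attention([bag])[0]
    assert np.allclose(a, a[0])
    assert np.all((a > 0) & (a < 1))  # ASU bound


def test_sum_aggregation_log_contract():
    # all attention frozen at 1, two instances with features (1,0) and (3,0):
    # aggregate must be (log1p(4), log1p(0)) = (log 5, 0)
    feats = np.array([[1.0, 0.0], [3.0, 0.0]])
    bag = Bag("b", {"x": feats}, label=0)
    other = Bag("o", {"x": np.array([[0.5, 0.5]])}, label=1)
    cfg = ModelConfig(
        aggregation="sum", freeze_attention=True, instance_dim=None,
        hidden=(), n_heads=1, seed=0,
    )
    m = MILClassifier([bag, other], [IdentityConcept("x", 2)], config=cfg)
    logits, _, _, _ = m._forward(m.data, np.array([0]))
    # recover the aggregate by inverting the (linear) output layer is fragile;
    # instead check the aggregation output directly
    f = Tensor(feats)
    a = Tensor(np.ones((2, 1)))
    agg = m._aggregate_heads(f, a, np.array([2]), "sum")
    np.testing.assert_allclose(agg.data, [[np.log(5.0), 0.0]])


def test_sum_mode_monotone_under_duplication():
    # duplicating a positively-attended instance never decreases the
    # pre-log per-head aggregate
    rng = np.random.default_rng(8)
    bags = random_bags(rng=rng)
    cfg = ModelConfig(aggregation="sum", instance_dim=8, seed=3)
    m = MILClassifier(bags, [CategoricalConcept("code", 10, 4)], config=cfg)
    bag = bags[0]
    dup = Bag(
        "dup",
        {k: np.concatenate([v, v[:1]]) for k, v in bag.instances.items()},
        label=bag.label,
    )
    for b_small, b_big in [(bag, dup)]:
        data_small = m.data.__class__([b_small], m.concept_names)
        data_big = m.data.__class__([b_big], m.concept_names)
        f1 = m._encode(data_small, np.arange(b_small.n_instances), False, rng)
        a1 = m.attn(f1)
        pre1 = (f1.data * a1.data[:, :1]).sum(axis=0)
        f2 = m._encode(data_big, np.arange(b_big.n_instances), False, rng)
        a2 = m.attn(f2)
        pre2 = (f2.data * a2.data[:, :1]).sum(axis=0)
        assert np.all(pre2 >= pre1 - 1e-12)


def test_multiclass_heads_default_to_n_classes():
    bags = random_bags(n_classes=4)
    m = MILClassifier(bags, [CategoricalConcept("code", 10, 4)], n_classes=4)
    assert m.n_heads == 4
    a = m.attention(bags)
    assert a[0].shape[1] == 4


def test_binary_defaults_to_single_head():
    bags = random_bags(n_classes=2)
    m = MILClassifier(bags, [CategoricalConcept("code", 10, 4)])
    assert m.binary and m.n_heads == 1


def test_empty_bag_rejected_at_evaluation():
    bags = random_bags()
    m = MILClassifier(bags, [CategoricalConcept("code", 10, 4)])
    empty = Bag("e", {"code": np.array([], dtype=int),
                      "onehot": np.empty((0, 10))}, label=0)
    with pytest.raises(ValueError, match="no instances"):
        m.predict_proba([empty])


def test_sample_features_concatenate_post_aggregation():
    rng = np.random.default_rng(4)
    bags = []
    for i in range(8):
        codes = rng.integers(0, 10, size=5)
        bags.append(
            Bag(
                sample_id=f"b{i}",
                instances={"code": codes},
                sample_features=rng.normal(size=3),
                label=int(i % 2),
            )
        )
    m = MILClassifier(bags, [CategoricalConcept("code", 10, 4)])
    p = m.predict_proba(bags)
    assert p.shape == (8, 2)
    # sample features must influence the prediction
    modified = [
        Bag(b.sample_id, b.instances, b.label, b.sample_features + 10.0)
        for b in bags
    ]
    assert not np.allclose(p, m.predict_proba(modified))


def test_dynamic_aggregation_uses_bag_context():
    rng = np.random.default_rng(9)
    bags = random_bags(rng=rng)
    cfg = ModelConfig(aggregation="dynamic", instance_dim=6, hidden=(8,), seed=0)
    m = MILClassifier(bags, [CategoricalConcept("code", 10, 4)], config=cfg)
    assert m.attn2 is not None
    # the same instance in different bag contexts can receive different
    # second-round attention
    codeA = np.array([0, 1, 2])
    codeB = np.array([0, 7, 8])
    a = m.attention([Bag("A", {"code": codeA, "onehot": np.eye(10)[codeA]}, 0),
                     Bag("B", {"code": codeB, "onehot": np.eye(10)[codeB]}, 0)])
    assert not np.allclose(a[0][0], a[1][0])


def test_save_load_round_trip(tmp_path):
    bags = random_bags()
    m = MILClassifier(bags, [CategoricalConcept("code", 10, 4)])
    p_before = m.predict_proba(bags)
    path = tmp_path / "w.npz"
    m.save_weights(path)
    m2 = MILClassifier(bags, [CategoricalConcept("code", 10, 4)])
    m2.out.W.data[...] = 1.0  # perturb
    m2.load_weights(path)
    np.testing.assert_allclose(m2.predict_proba(bags), p_before)


def test_msi_reference_config_shape():
    cfg = msi_reference_config()
    assert cfg.n_heads == 1
    assert cfg.instance_dropout == pytest.approx(0.4)
    assert cfg.attention_l1 == pytest.approx(0.05)
    assert cfg.hidden == (256, 128)
    spec = SequenceConceptSpec()
    assert spec.n_kernels == 8 and spec.fuse_dim == 128 and spec.l2 == 0.01


def test_construction_errors():
    bags = random_bags()
    with pytest.raises(ValueError):
        ModelConfig(instance_dropout=1.0)
    with pytest.raises(ValueError):
        ModelConfig(aggregation="median")
    with pytest.raises(TypeError):
        MILClassifier(bags, [object()])
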