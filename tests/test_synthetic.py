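import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.cluster import KMeans

from gclayers.matrix import standardize_genes
from gclayers.preprocess import impute_missing
from gclayers.synthetic import (
    DEFAULT_LAYER_SPECS,
    GroundTruth,
    LayerSpec,
    attach_survival,
    generate_cohort,
    inject_missing,
)
from gclayers.survival import kaplan_meier


class TestLayerSpec:
    def test_invalid_proportions(self):
        with pytest.raises(ValueError, match="sum"):
            LayerSpec(10, 2, group_props=(0.5, 0.4))
        with pytest.raises(ValueError, match="positive"):
            LayerSpec(10, 2, group_props=(1.0, 0.0))

    def test_default_specs_match_reported_blocks(self):
        sizes = [sp.n_genes for sp in DEFAULT_LAYER_SPECS]
        assert sizes == [118, 97, 46, 125, 116, 65, 104]
        assert [sp.n_groups for sp in DEFAULT_LAYER_SPECS] == [2] * 6 + [3]


class TestGenerateCohort:
    def test_shapes_and_partition(self):
        specs = [LayerSpec(118, 2), LayerSpec(97, 2), LayerSpec(125, 2)]
        m, truth = generate_cohort(
            n_samples=142, layer_specs=specs, n_background_genes=60, seed=0
        )
        assert m.n_genes == 118 + 97 + 125 + 60
        assert m.n_samples == 142
        # gene sets pairwise disjoint, union + background = full row set
        all_layer = set(itertools.chain.from_iterable(truth.layer_genes))
        assert sum(len(g) for g in truth.layer_genes) == len(all_layer)
        assert all_layer | set(truth.background_genes) == set(m.genes)

    def test_bit_reproducible(self):
        a, _ = generate_cohort(n_samples=30, layer_specs=[LayerSpec(10, 2)],
                               n_background_genes=5, seed=42)
        b, _ = generate_cohort(n_samples=30, layer_specs=[LayerSpec(10, 2)],
                               n_background_genes=5, seed=42)
        assert a.values.equals(b.values)

    def test_subtype_proportions_within_rounding(self):
        _, truth = generate_cohort(n_samples=142, layer_specs=[LayerSpec(20, 2)],
                                   n_background_genes=10, seed=3)
        counts = pd.Series(truth.subtype).value_counts()
        for name, prop in {"CIN": 0.542, "MSI": 0.190, "GS": 0.205, "EBV": 0.063}.items():
            assert abs(counts[name] - prop * 142) <= 1

    def test_no_signal_when_effect_zero(self):
        m, truth = generate_cohort(
            n_samples=80, layer_specs=[LayerSpec(30, 2, effect_size=0.0)],
            n_background_genes=0, noise_sd=1.0, seed=5, subtype_layers=(),
        )
        groups = np.array([truth.layer_labels[0][s] for s in m.samples])
        X = m.values.to_numpy()
        sep = np.abs(X[:, groups == 0].mean(1) - X[:, groups == 1].mean(1))
        # group-mean gaps are pure noise: ~N(0, sd*sqrt(1/n0+1/n1))
        assert sep.mean() < 4 * 1.0 * np.sqrt(2 / 40)

    def test_planted_labels_recovered_by_kmeans(self, planted_cohort):
        """δ=5, sd=0.5: k-means on the block genes matches ground truth
        exactly, measured by brute-force best-permutation agreement."""
        m, truth = planted_cohort
        block = standardize_genes(m.subset_genes(truth.layer_genes[0]))
        pred = KMeans(2, n_init=10, random_state=0).fit(block.values.to_numpy().T).labels_
        true = np.array([truth.layer_labels[0][s] for s in m.samples])
        best_agree = max(
            np.mean(np.vectorize(dict(enumerate(perm)).get)(pred) == true)
            for perm in itertools.permutations(range(2))
        )
        assert best_agree == 1.0

    def test_duplicate_proportion_error(self):
        with pytest.raises(ValueError, match="sum"):
            generate_cohort(n_samples=20, layer_specs=[LayerSpec(5, 2)],
                            subtype_props={"CIN": 0.6, "MSI": 0.6}, seed=0)


class TestInjectMissing:
    def test_rate_zero_identity(self, planted_cohort):
        m, _ = planted_cohort
        assert inject_missing(m, 0.0, seed=1).values.equals(m.values)

    def test_binomial_count(self, rng):
        from gclayers.matrix import ExpressionMatrix

        m = ExpressionMatrix(pd.DataFrame(
            rng.normal(size=(100, 100)),
            index=[f"G{i}" for i in range(100)],
            columns=[f"S{j}" for j in range(100)]))
        out = inject_missing(m, 0.25, seed=7)
        n_missing = out.n_missing
        assert abs(n_missing - 2500) <= 3 * np.sqrt(10000 * 0.25 * 0.75)
        # unmasked entries untouched
        keep = ~out.values.isna().to_numpy()
        assert np.array_equal(out.values.to_numpy()[keep], m.values.to_numpy()[keep])

    def test_rate_one_rejected(self, planted_cohort):
        with pytest.raises(ValueError):
            inject_missing(planted_cohort[0], 1.0, seed=0)

    def test_mask_then_unbiased_imputation(self):
        """Monte Carlo: with downshift 0 and width 1, the imputed entries'
        mean per column stays within 3 SE of that column's observed mean
        (~99.7% coverage over 50 seeds × 4 columns)."""
        from gclayers.matrix import ExpressionMatrix

        zs = []
        for seed in range(50):
            r = np.random.default_rng(seed)
            m = ExpressionMatrix(pd.DataFrame(
                r.normal(0, 1, size=(200, 4)),
                index=[f"G{i}" for i in range(200)],
                columns=list("ABCD")))
            masked = inject_missing(m, 0.3, seed=seed)
            imp = impute_missing(masked, width=1.0, downshift=0.0, seed=seed)
            for col in "ABCD":
                miss = masked.values[col].isna()
                obs = masked.values.loc[~miss, col]
                drawn = imp.values.loc[miss, col]
                se = obs.std(ddof=1) / np.sqrt(miss.sum())
                zs.append((drawn.mean() - obs.mean()) / se)
        zs = np.abs(np.array(zs))
        assert (zs <= 3).mean() >= 0.97


class TestAttachSurvival:
    def test_unknown_layer(self, planted_cohort):
        _, truth = planted_cohort
        with pytest.raises(KeyError):
            attach_survival(truth, driving_layer=5, log_hazard_ratios=(0, 1), seed=0)

    def test_all_censored_km_stays_at_one(self, planted_cohort):
        _, truth = planted_cohort
        clin = attach_survival(
            truth, 0, (0.0, 0.0), baseline_rate=1e-6, censor_rate=5.0, seed=0
        )
        assert clin["event"].sum() == 0
        curve = kaplan_meier(clin["os_months"], clin["event"])
        assert np.allclose(curve.survival, 1.0)
        assert curve.median is None

    def test_event_fraction_matches_competing_rates(self, planted_cohort):
        _, truth = planted_cohort
        clin = attach_survival(truth, 0, (0.0, 0.0),
                               baseline_rate=0.03, censor_rate=0.03, seed=1)
        # events and censorings equally likely
        frac = clin["event"].mean()
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / len(clin))


class TestGroundTruth:
    def test_json_roundtrip(self, tmp_path, planted_cohort):
        _, truth = planted_cohort
        path = tmp_path / "truth.json"
        truth.to_json(path)
        back = GroundTruth.from_json(path)
        assert back.layer_genes == truth.layer_genes
        assert back.layer_labels == truth.layer_labels
        assert back.subtype == truth.subtype

    def test_overlapping_layers_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            GroundTruth(
                layer_genes=[["G1", "G2"], ["G2", "G3"]],
                layer_labels=[{"S1": 0}, {"S1": 0}],
                subtype={"S1": "CIN"},
                background_genes=[],
            )
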