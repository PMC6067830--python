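"""Circuit construction: manifests, sampling distributions, sign discipline."""

import numpy as np
import pytest
from scipy import stats

from empathynet.circuit import (
    CircuitConfigError,
    GradientSpec,
    Projection,
    build_empathy_circuit,
    build_self_attachment_circuit,
    load_packaged_config,
    realize_circuit,
    sample_mpfc_gradient_targets,
    sample_projection,
)


class TestBuilders:
    def test_empathy_circuit_has_eleven_regions_and_manifest_edges(self):
        model = build_empathy_circuit()
        assert len(model.regions) == 11
        assert "mOFC" not in model.regions
        edges = model.inter_edges
        assert ("BLMA_neg", "AI", "excitatory") in edges
        assert ("mPFC", "mPOA", "excitatory") in edges
        assert ("VTA", "NAc", "inhibitory") in edges
        assert ("NAc", "VP", "inhibitory") in edges
        assert ("BLMA_i", "BLMA_neg", "inhibitory") in edges

    def test_self_attachment_is_empathy_plus_mofc(self):
        emp = build_empathy_circuit()
        sa = build_self_attachment_circuit()
        assert set(sa.regions) - set(emp.regions) == {"mOFC"}
        extra = sa.inter_edges - emp.inter_edges
        assert extra == {
            ("mOFC", "AI", "excitatory"),
            ("mOFC", "BLMA_i", "excitatory"),
            ("mOFC", "BLMA_pos", "excitatory"),
        }

    def test_missing_region_error_names_it(self):
        config = load_packaged_config("empathy")
        del config["regions"]["VP"]
        with pytest.raises(CircuitConfigError, match="VP"):
            build_empathy_circuit(config)

    def test_probability_outside_unit_interval_rejected(self):
        config = load_packaged_config("empathy")
        config["projections"][0]["p"] = 1.5
        with pytest.raises(CircuitConfigError, match=r"outside \[0, 1\]"):
            build_empathy_circuit(config)

    def test_inhibitory_source_must_form_inhibitory_projection(self):
        config = load_packaged_config("empathy")
        config["projections"].append(
            dict(source="BLMA_i.inh", target="VP", sign="excitatory", p=0.1, w=1.0))
        with pytest.raises(CircuitConfigError, match="inhibitory source"):
            build_empathy_circuit(config)

    def test_extra_edge_absent_from_manifest_rejected(self):
        config = load_packaged_config("empathy")
        config["projections"].append(
            dict(source="aMCC.exc", target="VP", sign="excitatory", p=0.1, w=1.0))
        with pytest.raises(CircuitConfigError, match="absent from manifest"):
            build_empathy_circuit(config)

    def test_weight_overrides_apply(self):
        model = build_empathy_circuit(overrides={"NAc.inh->VP": 9.25})
        proj = next(p for p in model.projections if p.key == "NAc.inh->VP")
        assert proj.weight == 9.25


class TestSampleProjection:
    def _proj(self, p):
        return Projection("AI.exc", "PI", "excitatory", p, 1.0)

    def test_probability_one_saturates(self, rng):
        src, tgt = sample_projection(self._proj(1.0), 10, 10, rng)
        assert len(src) == 100
        assert len(set(zip(src.tolist(), tgt.tolist()))) == 100

    def test_probability_zero_empty(self, rng):
        src, tgt = sample_projection(self._proj(0.0), 10, 10, rng)
        assert len(src) == 0

    def test_binomial_moments(self):
        counts = [
            len(sample_projection(self._proj(0.1), 100, 100,
                                  np.random.default_rng(seed))[0])
            for seed in range(200)
        ]
        se = np.sqrt(10000 * 0.1 * 0.9 / 200)
        assert abs(np.mean(counts) - 1000) < 3 * se


class TestGradientSampling:
    def test_untruncated_means_match_closed_form(self, rng):
        spec = GradientSpec()
        # huge index space => effectively untruncated draws
        for which, (r, p) in (("distant", (14, 0.035)), ("close", (7, 0.0025))):
            draws = sample_mpfc_gradient_targets(spec, which, 10**6, 100_000, rng)
            expected = r * (1 - p) / p
            assert abs(np.mean(draws) - expected) / expected < 0.02

    def test_close_and_distant_occupy_distinct_bands(self, rng):
        spec = GradientSpec()
        close = sample_mpfc_gradient_targets(spec, "close", 2000, 10_000, rng)
        distant = sample_mpfc_gradient_targets(spec, "distant", 2000, 10_000, rng)
        # ventral (high-index) close band vs dorsal distant band
        assert np.mean(close) > np.mean(distant)
        stat = stats.mannwhitneyu(close, distant, alternative="greater")
        assert stat.pvalue < 1e-3

    def test_draws_respect_range_and_uniqueness(self, rng):
        spec = GradientSpec()
        draws = sample_mpfc_gradient_targets(spec, "close", 1500, 400, rng, unique=True)
        assert len(draws) == 400
        assert len(np.unique(draws)) == 400
        assert draws.min() >= 0 and draws.max() < 1500

    def test_axis_orientation_flips_band(self, rng):
        lo_spec = GradientSpec(axis_orientation="ventral_at_low_index")
        hi_spec = GradientSpec(axis_orientation="ventral_at_high_index")
        lo = sample_mpfc_gradient_targets(lo_spec, "distant", 2000, 5000, rng)
        hi = sample_mpfc_gradient_targets(hi_spec, "distant", 2000, 5000, rng)
        assert np.mean(lo) > 1000 > np.mean(hi)

    def test_degenerate_gradient_rejected(self):
        with pytest.raises(CircuitConfigError, match="degenerate"):
            GradientSpec(close_other=(7, 1.5))


class TestRealization:
    def test_seeded_reproducibility(self):
        model = build_empathy_circuit()
        a = realize_circuit(model, np.random.default_rng(7))
        b = realize_circuit(model, np.random.default_rng(7))
        assert a.synapse_count == b.synapse_count
        assert (a.weights != b.weights).nnz == 0

    def test_sign_discipline_in_realized_matrix(self):
        model = build_self_attachment_circuit()
        rc = realize_circuit(model, np.random.default_rng(0))
        W = rc.weights.tocsc()
        # every inhibitory-source column is non-positive; includes the
        # dopaminergic VTA projection, which is inhibitory-signed by design
        for region, which in [("BLMA_i", "inh"), ("NAc", "inh"), ("VTA", "exc")]:
            sl = rc.subpop_slices[(region, which)]
            block = W[:, sl.start:sl.stop]
            if region == "VTA":
                # inter-region part (to NAc) must be negative, intra positive-free
                nac = rc.region_slices["NAc"]
                assert (W[nac.start:nac.stop, sl.start:sl.stop].data <= 0).all()
            else:
                assert (block.data <= 0).all()

    def test_neuron_layout_and_types(self):
        model = build_empathy_circuit()
        rc = realize_circuit(model, np.random.default_rng(0))
        vp = rc.subpop_slices[("VP", "inh")]
        assert rc.a[vp.start] == 0.1  # fast-spiking VP
        vta = rc.subpop_slices[("VTA", "exc")]
        assert rc.c[vta.start] == -55.0  # intrinsically bursting VTA
        assert rc.n_neurons == sum(r.size for r in model.regions.values())
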