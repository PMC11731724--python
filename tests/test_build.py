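"""Network construction: channels, pathways, scaling and realization."""

import numpy as np
import pytest

from cbgtsim.build import (
    PathwaySpec,
    apply_newpathways,
    build_network,
    build_spec,
    resolve_population_name,
    scale_shared_inputs,
)
from cbgtsim.core import ConfigError
from cbgtsim.engine import RealizedNetwork, _draw_adjacency
from cbgtsim.params import SHARED_POPS


class TestSpecAssembly:
    def test_two_channels_replicate_all_but_shared_pools(self):
        net = build_network(channels=["left", "right"], seed=0)
        labels = [inst.label for inst in net.instances]
        assert labels.count("FSI") == 1 and labels.count("CxI") == 1
        for pop in ("Cx", "dSPN", "iSPN", "GPeP", "GPeA", "STN", "GPi", "Th"):
            assert {f"{pop}_left", f"{pop}_right"} <= set(labels)

    def test_three_channels_still_share_fsi_and_cxi(self):
        net = build_network(channels=["A", "B", "C"], seed=0)
        shared = [i for i in net.instances if i.pop in SHARED_POPS]
        assert len(shared) == 2
        assert sum(1 for i in net.instances if i.pop == "Th") == 3

    def test_duplicate_channel_labels_rejected(self):
        with pytest.raises(ConfigError):
            build_spec(channels=["left", "left"])

    def test_gpe_alias_resolves_to_prototypical(self):
        assert resolve_population_name("GPe") == "GPeP"
        with pytest.raises(ConfigError, match="valid names"):
            resolve_population_name("NoSuchNucleus")


class TestAdjacency:
    def test_full_connectivity_is_complete_bipartite(self, rng):
        adj = _draw_adjacency(rng, 5, 7, con=1.0)
        assert adj.sum() == 35
        assert np.all(adj == 1.0)

    def test_expected_count_at_half_probability(self, rng):
        adj = _draw_adjacency(rng, 50, 50, con=0.5)
        # fixed in-degree: every postsynaptic cell receives exactly 25
        assert np.all(adj.sum(axis=0) == 25)
        assert adj.sum() == 1250

    def test_no_self_connections(self, rng):
        adj = _draw_adjacency(rng, 20, 20, con=1.0, same=True)
        assert np.all(np.diag(adj) == 0)
        assert np.all(adj.sum(axis=0) == 19)

    def test_same_seed_reproduces_identical_adjacency(self):
        a = build_network(channels=["left", "right"], seed=11)
        b = build_network(channels=["left", "right"], seed=11)
        for r in ("AMPA", "NMDA", "GABA"):
            assert np.array_equal(a.W[r], b.W[r])

    def test_different_seed_changes_adjacency(self):
        a = build_network(channels=["left", "right"], seed=11)
        b = build_network(channels=["left", "right"], seed=12)
        assert any(not np.array_equal(a.W[r], b.W[r]) for r in ("AMPA", "GABA"))


class TestNewPathways:
    def test_empty_table_leaves_spec_unchanged(self):
        spec = build_spec(channels=["left"])
        out = apply_newpathways(spec, None)
        assert [p.key for p in out.pathways] == [p.key for p in spec.pathways]

    def test_printed_corticopallidal_row_is_added(self):
        spec = build_spec(channels=["left"])
        out = apply_newpathways(spec, [["Cx", "GPe", "AMPA", "syn", 0.5, 0.01, False]])
        added = [p for p in out.pathways if p.key == ("Cx", "GPeP", "AMPA")]
        assert len(added) == 1
        p = added[0]
        assert (p.con, p.eff, p.plastic, p.type) == (0.5, 0.01, False, "syn")

    def test_override_changes_only_named_fields(self):
        spec = build_spec(channels=["left"])
        target = next(p for p in spec.pathways if p.key == ("GPi", "Th", "GABA"))
        out = apply_newpathways(
            spec, [["GPi", "Th", "GABA", target.type, target.con, 0.5, False]]
        )
        changed = next(p for p in out.pathways if p.key == ("GPi", "Th", "GABA"))
        assert changed.eff == 0.5 and changed.con == target.con
        assert len(out.pathways) == len(spec.pathways)

    def test_eff_override_with_same_con_keeps_topology(self):
        spec = build_spec(channels=["left"])
        target = next(p for p in spec.pathways if p.key == ("GPi", "Th", "GABA"))
        a = RealizedNetwork(spec, seed=5)
        spec2 = apply_newpathways(
            spec, [["GPi", "Th", "GABA", target.type, target.con, target.eff * 3, False]]
        )
        b = RealizedNetwork(spec2, seed=5)
        mask_a = a.W["GABA"] != 0
        mask_b = b.W["GABA"] != 0
        assert np.array_equal(mask_a, mask_b)

    def test_malformed_row_reports_index(self):
        spec = build_spec(channels=["left"])
        with pytest.raises(ConfigError, match="row 1"):
            apply_newpathways(spec, [["Cx", "GPe", "AMPA", "syn", 0.5, 0.01, False],
                                     ["Cx", "GPe", "AMPA"]])

    def test_unknown_population_lists_valid_names(self):
        with pytest.raises(ConfigError, match="valid names"):
            PathwaySpec("Cortex", "GPe", "AMPA", "syn", 0.5, 0.01, False)


class TestSharedInputScaling:
    def test_single_channel_is_identity(self):
        spec = build_spec(channels=["left"])
        out = scale_shared_inputs(spec, 1)
        assert [p.eff for p in out.pathways] == [p.eff for p in spec.pathways]

    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_channelized_to_shared_efficacy_divided_by_n(self, n):
        spec = build_spec(channels=[str(i) for i in range(n)])
        out = scale_shared_inputs(spec, n)
        for before, after in zip(spec.pathways, out.pathways):
            if before.src not in SHARED_POPS and (
                before.dest in SHARED_POPS or before.type == "common"
            ):
                assert after.eff == pytest.approx(before.eff / n)
            else:
                assert after.eff == before.eff

    def test_expected_drive_onto_shared_pools_invariant(self):
        """Sum of (in-degree x efficacy) onto FSI/CxI is independent of n."""
        totals = {}
        for n in (1, 2, 4):
            channels = [str(i) for i in range(n)]
            net = build_network(channels=channels, seed=3)
            for pop in ("FSI", "CxI"):
                sl = net.instance(pop).sl
                drive = sum(net.W[r][:, sl].sum() for r in ("AMPA", "NMDA", "GABA"))
                drive /= sl.stop - sl.start
                totals.setdefault(pop, {})[n] = drive
        for pop, by_n in totals.items():
            ref = by_n[1]
            for n, v in by_n.items():
                assert v == pytest.approx(ref, rel=0.05), (pop, n)

    def test_invalid_channel_count_rejected(self):
        spec = build_spec(channels=["left"])
        with pytest.raises(ConfigError):
            scale_shared_inputs(spec, 0)
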