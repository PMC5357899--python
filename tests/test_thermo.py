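import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sirnafusion as sf
from sirnafusion.sequence_io import reverse_complement
from sirnafusion.thermo import (
    EnergyCache,
    InteractionEnergies,
    duplex_energy,
    end_asymmetry,
    hybridization_energy,
    interaction_energies,
    parse_rnaup_output,
    render_rnaup_output,
    stack_energies,
)

core19 = st.text(alphabet="ACGU", min_size=19, max_size=19)


def brute_stack_sum(core, table):
    """Independent plain-loop nearest-neighbor sum."""
    total = 0.0
    for i in range(len(core) - 1):
        total += table.stacks[core[i: i + 2]]
    return total


class TestStackEnergies:
    def test_homopolymer_lookup(self, nn_table):
        assert stack_energies("A" * 19, nn_table) == [nn_table.stacks["AA"]] * 18
        assert stack_energies("G" * 19, nn_table) == [nn_table.stacks["GG"]] * 18

    def test_wrong_length_errors(self, nn_table):
        with pytest.raises(ValueError):
            stack_energies("A" * 18, nn_table)
        with pytest.raises(ValueError):
            duplex_energy("", nn_table)

    def test_strand_symmetry_of_table(self, nn_table):
        # a stack read from the complementary strand is the same physical stack
        for dinuc, value in nn_table.stacks.items():
            assert value == nn_table.stacks[reverse_complement(dinuc)]

    @settings(deadline=None, max_examples=200)
    @given(core=core19)
    def test_duplex_is_sum_of_stacks(self, core, nn_table):
        stacks = stack_energies(core, nn_table)
        assert duplex_energy(core, nn_table) == sum(stacks)
        assert duplex_energy(core, nn_table) == pytest.approx(
            brute_stack_sum(core, nn_table), abs=0
        )


class TestEndAsymmetry:
    @pytest.mark.parametrize("base", "ACGU")
    def test_homopolymer_is_zero(self, base, nn_table):
        assert end_asymmetry(base * 19, nn_table) == 0.0

    def test_terminal_window_hand_sum(self, nn_table):
        # 5 G's, then an A/U-alternating interior, then 5 A's
        core = "GGGGG" + "AUAUAUAUA" + "AAAAA"
        expected = (
            4 * nn_table.stacks["GG"] - 4 * nn_table.stacks["AA"]
            # boundary stacks GA (pos 5-6) and AA (14-15) lie outside windows
        )
        # windows: stacks 1-4 (GG x4) and stacks 15-18 (AA x4)
        assert end_asymmetry(core, nn_table) == pytest.approx(expected)

    def test_reversal_negates_for_symmetric_interior(self, nn_table):
        core = "GGGGG" + "CCCCCCCCC" + "AAAAA"
        reverse = core[::-1]
        assert end_asymmetry(reverse, nn_table) == pytest.approx(
            -end_asymmetry(core, nn_table)
        )

    @settings(deadline=None, max_examples=100)
    @given(core=core19)
    def test_au_to_gc_strengthens_five_prime_window(self, core, nn_table):
        """Replacing an A in the 5' window with G never weakens (raises) the
        window sum under the shipped parameters."""
        if "A" not in core[:5]:
            return
        i = core[:5].index("A")
        mutated = core[:i] + "G" + core[i + 1:]
        orig = sum(stack_energies(core, nn_table)[:4])
        new = sum(stack_energies(mutated, nn_table)[:4])
        assert new < orig


class TestHybridizationEnergy:
    def test_perfect_complement_oracle(self, nn_table):
        core = "A" * 19
        site = reverse_complement(core)
        expected = nn_table.initiation + 18 * nn_table.stacks["AA"]
        assert hybridization_energy(core, site, nn_table) == pytest.approx(expected)

    def test_gc_rich_binds_tighter_than_au_rich(self, nn_table):
        gc = "GC" * 9 + "G"
        au = "AU" * 9 + "A"
        e_gc = hybridization_energy(gc, reverse_complement(gc), nn_table)
        e_au = hybridization_energy(au, reverse_complement(au), nn_table)
        assert e_gc <= e_au

    def test_negative_for_any_complementary_duplex(self, nn_table):
        rng = np.random.default_rng(0)
        for _ in range(20):
            core = "".join(rng.choice(list("ACGU"), 19))
            assert hybridization_energy(core, reverse_complement(core), nn_table) < 0

    def test_mismatched_site_errors(self, nn_table):
        with pytest.raises(ValueError, match="RNAup"):
            hybridization_energy("A" * 19, "G" * 19, nn_table)


class TestRnaupParser:
    def test_two_term_decomposition(self):
        energies, total = parse_rnaup_output(
            "GUACGU&ACGUAC  5,10 : 1,6 (-5.44 = -7.18 + 1.74)"
        )
        assert energies == InteractionEnergies(dg_s=0.0, dg_m=1.74, dg_h=-7.18)
        assert total == -5.44

    def test_three_term_decomposition_sum_consistent(self):
        energies, total = parse_rnaup_output(
            "((((&))))  15,32 : 1,18  (-6.31 = -32.20 + 17.80 + 8.09)"
        )
        assert energies.dg_h == -32.20
        assert energies.dg_m == 17.80
        assert energies.dg_s == 8.09
        assert total == pytest.approx(energies.total, abs=0.011)

    def test_empty_text_errors(self):
        with pytest.raises(ValueError):
            parse_rnaup_output("")

    @settings(deadline=None, max_examples=100)
    @given(
        dg_s=st.floats(0, 30), dg_m=st.floats(0, 30), dg_h=st.floats(-60, 0)
    )
    def test_render_parse_round_trip(self, dg_s, dg_m, dg_h):
        original = InteractionEnergies(
            dg_s=round(dg_s, 2), dg_m=round(dg_m, 2), dg_h=round(dg_h, 2)
        )
        parsed, _ = parse_rnaup_output(render_rnaup_output(original))
        assert parsed == original


class TestInteractionBackends:
    def test_fallback_is_nearest_neighbor_sum(self, nn_table):
        record = sf.SirnaRecord("s1", "A" * 19 + "UU", "m1")
        context = sf.locate_binding_site(record, "GG" + "U" * 19 + "GG")
        energies = interaction_energies(record, context, backend="fallback")
        assert energies.dg_s == energies.dg_m == 0.0
        assert energies.dg_h == pytest.approx(
            hybridization_energy("A" * 19, "U" * 19, nn_table)
        )

    def test_unknown_backend_errors(self):
        record = sf.SirnaRecord("s1", "A" * 19 + "UU", "m1")
        context = sf.locate_binding_site(record, "U" * 25)
        with pytest.raises(ValueError, match="backend"):
            interaction_energies(record, context, backend="quantum")

    def test_cache_short_circuits_computation(self, tmp_path):
        record = sf.SirnaRecord("s1", "A" * 19 + "UU", "m1")
        context = sf.locate_binding_site(record, "GG" + "U" * 19 + "GG")
        cache = EnergyCache()
        planted = InteractionEnergies(dg_s=1.0, dg_m=2.0, dg_h=-9.0)
        cache.put(record.guide, context.target_id, context.binding_site[0], planted)
        assert interaction_energies(record, context, cache=cache) == planted
        # round-trip the cache file
        path = tmp_path / "cache.tsv"
        cache.save(path)
        reloaded = EnergyCache(path)
        assert reloaded.get(record.guide, "m1", 2) == planted
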