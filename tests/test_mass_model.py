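import itertools
import math

import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from nativems.mass_model import (
    AVERAGE_RESIDUE_MASSES,
    AssemblyRules,
    ComplexComposition,
    PtmRule,
    SubunitSpec,
    attach_ptm_rules,
    composition_label,
    composition_mass,
    enumerate_compositions,
    read_assembly_rules,
    read_ptm_rules_tsv,
    read_subunits_fasta,
    sequence_average_mass,
    write_compositions_tsv,
    write_subunits_fasta,
)

# standard atomic weights, for elemental-formula oracles
_W = {"C": 12.011, "H": 1.008, "N": 14.007, "O": 15.999, "S": 32.06}


def formula_mass(formula: dict) -> float:
    return sum(_W[el] * n for el, n in formula.items())


class TestSequenceAverageMass:
    def test_glycine_matches_elemental_formula(self):
        # free glycine is C2H5NO2
        expected = formula_mass({"C": 2, "H": 5, "N": 1, "O": 2})
        assert sequence_average_mass("G") == pytest.approx(expected, abs=0.01)

    def test_diglycine(self):
        # two G residues plus one water: C4H8N2O3
        expected = formula_mass({"C": 4, "H": 8, "N": 2, "O": 3})
        assert sequence_average_mass("GG") == pytest.approx(expected, abs=0.01)
        assert sequence_average_mass("GG") == pytest.approx(132.12, abs=0.01)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sequence_average_mass("")

    def test_unknown_residue_names_char_and_position(self):
        with pytest.raises(ValueError, match=r"'X' at position 3"):
            sequence_average_mass("GGXG")

    @given(
        a=st.text(alphabet=sorted(AVERAGE_RESIDUE_MASSES), min_size=1, max_size=30),
        b=st.text(alphabet=sorted(AVERAGE_RESIDUE_MASSES), min_size=1, max_size=30),
    )
    def test_additive_over_concatenation_minus_water(self, a, b):
        lhs = sequence_average_mass(a + b)
        rhs = sequence_average_mass(a) + sequence_average_mass(b) - 18.01528
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_strictly_positive(self):
        assert sequence_average_mass("W") > 0


class TestResolveSubunitMass:
    def test_single_bilin_adduct(self, fixed_registry):
        s = SubunitSpec(id="x", role="alpha", fixed_mass=17000.0,
                        ptms=(PtmRule("PCB", 586.7, 1),))
        from nativems.mass_model import resolve_subunit_mass
        assert resolve_subunit_mass(s) == pytest.approx(17586.7)

    def test_bilin_plus_met_loss(self, fixed_registry):
        from nativems.mass_model import resolve_subunit_mass
        assert resolve_subunit_mass(fixed_registry["A"]) == pytest.approx(17455.5)

    def test_two_bilins_with_methylation(self, fixed_registry):
        from nativems.mass_model import resolve_subunit_mass
        assert resolve_subunit_mass(fixed_registry["B"]) == pytest.approx(18187.4)

    def test_no_ptms_identity(self):
        from nativems.mass_model import resolve_subunit_mass
        s = SubunitSpec(id="x", role="alpha", fixed_mass=12345.6)
        assert resolve_subunit_mass(s) == pytest.approx(12345.6)

    def test_requires_exactly_one_mass_source(self):
        with pytest.raises(ValueError, match="exactly one"):
            SubunitSpec(id="x", role="alpha")
        with pytest.raises(ValueError, match="exactly one"):
            SubunitSpec(id="x", role="alpha", sequence="GG", fixed_mass=100.0)

    def test_ptm_validation(self):
        with pytest.raises(ValueError):
            PtmRule("bad", 1.0, -1)
        with pytest.raises(ValueError):
            PtmRule("bad", float("nan"), 1)


class TestCompositionMass:
    def test_singleton(self, fixed_registry):
        assert composition_mass({"A": 1}, fixed_registry) == pytest.approx(17455.5)

    def test_hand_summed_trimer_pair(self, fixed_registry):
        # 3*17455.5 + 3*18187.4
        assert composition_mass({"A": 3, "B": 3}, fixed_registry) == pytest.approx(
            106928.7
        )

    def test_empty_rejected(self, fixed_registry):
        with pytest.raises(ValueError, match="empty"):
            composition_mass({}, fixed_registry)

    def test_unknown_id_rejected(self, fixed_registry):
        with pytest.raises(KeyError, match="Z"):
            composition_mass({"Z": 1}, fixed_registry)

    @given(
        na=st.integers(0, 4), nb=st.integers(0, 4),
        ma=st.integers(0, 4), mb=st.integers(0, 4),
    )
    @settings(suppress_health_check=[HealthCheck.function_scoped_fixture])
    def test_mass_additivity_over_disjoint_union(self, fixed_registry, na, nb, ma, mb):
        left = {k: v for k, v in (("A", na), ("B", nb)) if v}
        right = {k: v for k, v in (("A", ma), ("B", mb)) if v}
        if not left or not right:
            return
        union = {k: left.get(k, 0) + right.get(k, 0) for k in set(left) | set(right)}
        total = composition_mass(union, fixed_registry)
        parts = composition_mass(left, fixed_registry) + composition_mass(
            right, fixed_registry
        )
        assert math.isclose(total, parts, rel_tol=1e-9)


def _inventory(n_sources=1, n_alpha_variants=0, linker=False, cross_family=False):
    inv = []
    base = 17000.0
    k = 0
    for s in range(1, n_sources + 1):
        src = f"s{s}"
        inv.append(SubunitSpec(id=f"a{s}", role="alpha", species=src,
                               fixed_mass=base + 400 * k)); k += 1
        inv.append(SubunitSpec(id=f"b{s}", role="beta", species=src,
                               fixed_mass=base + 400 * k)); k += 1
        for v in range(n_alpha_variants):
            inv.append(SubunitSpec(id=f"aB{s}", role="alpha_variant", species=src,
                                   fixed_mass=base + 400 * k)); k += 1
    if linker:
        inv.append(SubunitSpec(id="L", role="linker", species="s1", fixed_mass=7800.0))
    if cross_family:
        inv.append(SubunitSpec(id="pa", role="alpha", species="s1", family="PC",
                               fixed_mass=base + 400 * k)); k += 1
        inv.append(SubunitSpec(id="pb", role="beta", species="s1", family="PC",
                               fixed_mass=base + 400 * k)); k += 1
    return inv


class TestEnumerateCompositions:
    def test_variant_substitution_yields_four_trimers(self):
        inv = _inventory(n_alpha_variants=1)
        rules = AssemblyRules(oligomer_states={3},
                              max_variant_substitutions={"alpha_variant": 3})
        comps = enumerate_compositions(inv, rules)
        labels = sorted(c.label for c in comps)
        assert labels == ["2aB1.a1.3b1", "3a1.3b1", "3aB1.3b1", "aB1.2a1.3b1"]

    def test_two_source_mixing_yields_four_trimers(self):
        inv = _inventory(n_sources=2)
        rules = AssemblyRules(oligomer_states={3}, allow_cross_source_protomers=True)
        comps = enumerate_compositions(inv, rules)
        labels = sorted(c.label for c in comps)
        assert labels == [
            "2a1.a2.2b1.b2", "3a1.3b1", "3a2.3b2", "a1.2a2.b1.2b2",
        ]

    def test_monomer_trimer_and_linker(self):
        inv = _inventory(linker=True)
        rules = AssemblyRules(oligomer_states={1, 3}, linker_max_copies=1,
                              linker_attach_states={3})
        labels = sorted(c.label for c in enumerate_compositions(inv, rules))
        assert labels == ["3a1.3b1", "3a1.3b1+L", "a1.b1"]

    def test_cross_family_hybrids_enumerated_by_default(self):
        inv = _inventory(cross_family=True)
        rules = AssemblyRules(oligomer_states={3})
        labels = {c.label for c in enumerate_compositions(inv, rules)}
        # pure trimers from both families plus the two mixed-protomer hybrids
        assert "3a1.3b1" in labels and "3pa.3pb" in labels
        assert "2a1.pa.2b1.pb" in labels and "a1.2pa.b1.2pb" in labels

    def test_cross_family_mixing_can_be_disabled(self):
        inv = _inventory(cross_family=True)
        rules = AssemblyRules(oligomer_states={3}, allow_cross_family_protomers=False)
        labels = {c.label for c in enumerate_compositions(inv, rules)}
        assert labels == {"3a1.3b1", "3pa.3pb"}

    def test_missing_beta_rejected(self):
        inv = [SubunitSpec(id="a1", role="alpha", fixed_mass=17000.0)]
        with pytest.raises(ValueError, match="lacks"):
            enumerate_compositions(inv, AssemblyRules())

    @pytest.mark.parametrize("n", [1, 2, 3, 4])
    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_mixing_count_matches_brute_force_and_closed_form(self, n, k):
        inv = _inventory(n_sources=k)
        rules = AssemblyRules(oligomer_states={n}, allow_cross_source_protomers=True)
        comps = enumerate_compositions(inv, rules)
        # independent brute force: every assignment of n ring slots to k
        # protomer types, deduplicated as a member multiset
        protomers = [(f"a{s}", f"b{s}") for s in range(1, k + 1)]
        seen = set()
        for slots in itertools.product(range(k), repeat=n):
            members: dict[str, int] = {}
            for slot in slots:
                a, b = protomers[slot]
                members[a] = members.get(a, 0) + 1
                members[b] = members.get(b, 0) + 1
            seen.add(tuple(sorted(members.items())))
        assert len(comps) == len(seen) == math.comb(n + k - 1, k - 1)
        assert {tuple(sorted(c.members)) for c in comps} == seen

    @pytest.mark.parametrize("s", [0, 1, 2, 3])
    def test_substitution_count_closed_form(self, s):
        inv = _inventory(n_alpha_variants=1)
        rules = AssemblyRules(oligomer_states={3},
                              max_variant_substitutions={"alpha_variant": s})
        comps = enumerate_compositions(inv, rules)
        assert len(comps) == s + 1

    def test_determinism(self):
        inv = _inventory(n_sources=2, n_alpha_variants=1, linker=True)
        rules = AssemblyRules(allow_cross_source_protomers=True)
        first = enumerate_compositions(inv, rules)
        second = enumerate_compositions(inv, rules)
        assert [(c.label, c.theoretical_mass) for c in first] == [
            (c.label, c.theoretical_mass) for c in second
        ]

    def test_theoretical_mass_consistent_with_members(self, fixed_registry):
        comp = ComplexComposition.from_members({"A": 3, "B": 3}, fixed_registry)
        assert comp.theoretical_mass == pytest.approx(
            composition_mass(dict(comp.members), fixed_registry)
        )


class TestLabels:
    def test_label_orders_variant_before_base(self, fixed_registry):
        reg = dict(fixed_registry)
        reg["V"] = SubunitSpec(id="V", role="alpha_variant", fixed_mass=17900.0)
        assert composition_label({"A": 1, "B": 3, "V": 2}, reg) == "2V.A.3B"

    def test_label_is_input_order_independent(self, fixed_registry):
        l1 = composition_label({"A": 3, "B": 3}, fixed_registry)
        l2 = composition_label({"B": 3, "A": 3}, fixed_registry)
        assert l1 == l2 == "3A.3B"


class TestFileInterfaces:
    def test_fasta_roundtrip(self, tmp_path):
        inv = [
            SubunitSpec(id="a1", role="alpha", species="spX", family="PC",
                        sequence="ACDEFGHIKLMNPQRSTVWY" * 5),
            SubunitSpec(id="b1", role="beta", species="spX",
                        sequence="GGMMLLKK" * 10),
        ]
        path = tmp_path / "subs.fasta"
        write_subunits_fasta(inv, path)
        back = read_subunits_fasta(path)
        assert [(s.id, s.species, s.role, s.family, s.sequence) for s in back] == [
            (s.id, s.species, s.role, s.family, s.sequence) for s in inv
        ]

    def test_ptm_tsv_and_attach(self, tmp_path):
        path = tmp_path / "ptms.tsv"
        path.write_text(
            "subunit_id\tptm_name\tdelta_mass\tcount\n"
            "a1\tPCB\t586.7\t1\n"
            "a1\tMet-loss\t-131.2\t1\n"
        )
        rules = read_ptm_rules_tsv(path)
        assert rules["a1"][0] == PtmRule("PCB", 586.7, 1)
        inv = [SubunitSpec(id="a1", role="alpha", fixed_mass=17000.0)]
        from nativems.mass_model import resolve_subunit_mass
        out = attach_ptm_rules(inv, rules)
        assert resolve_subunit_mass(out[0]) == pytest.approx(17455.5)

    def test_assembly_rules_file(self, tmp_path):
        path = tmp_path / "rules.cfg"
        path.write_text(
            "oligomer_states = 1,3\n"
            "max_substitutions.alpha_variant = 3\n"
            "linker_max_copies = 1\n"
            "allow_cross_source_protomers = true\n"
        )
        rules = read_assembly_rules(path)
        assert rules.oligomer_states == frozenset({1, 3})
        assert rules.max_variant_substitutions == {"alpha_variant": 3}
        assert rules.allow_cross_source_protomers is True

    def test_compositions_tsv(self, tmp_path, fixed_registry):
        comps = [ComplexComposition.from_members({"A": 3, "B": 3}, fixed_registry)]
        path = tmp_path / "comps.tsv"
        write_compositions_tsv(comps, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "label\tmembers\ttheoretical_mass"
        assert lines[1].startswith("3A.3B\tA:3,B:3\t106928.7")
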