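"""PTM-adjusted subunit masses and combinatorial complex enumeration.

Average (not monoisotopic) masses are used throughout: the species of
interest are 1e4-1e5 Da non-covalent complexes measured at modest resolving
power, and the standard chromophore/processing mass deltas (+586.7 Da
bilin, -131.2 Da initiator-Met loss, +14 Da methylation) are themselves
average masses.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "AVERAGE_RESIDUE_MASSES",
    "WATER_MASS",
    "PtmRule",
    "SubunitSpec",
    "ComplexComposition",
    "AssemblyRules",
    "sequence_average_mass",
    "resolve_subunit_mass",
    "composition_label",
    "composition_mass",
    "enumerate_compositions",
    "read_subunits_fasta",
    "write_subunits_fasta",
    "read_ptm_rules_tsv",
    "attach_ptm_rules",
    "read_assembly_rules",
    "write_compositions_tsv",
]

#: Average masses of amino-acid residues (polymerised, i.e. minus water),
#: computed from IUPAC standard atomic weights.
AVERAGE_RESIDUE_MASSES: dict[str, float] = {
    "G": 57.0519,
    "A": 71.0788,
    "S": 87.0782,
    "P": 97.1167,
    "V": 99.1326,
    "T": 101.1051,
    "C": 103.1388,
    "L": 113.1594,
    "I": 113.1594,
    "N": 114.1038,
    "D": 115.0886,
    "Q": 128.1307,
    "K": 128.1741,
    "E": 129.1155,
    "M": 131.1926,
    "H": 137.1411,
    "F": 147.1766,
    "R": 156.1875,
    "Y": 163.1760,
    "W": 186.2132,
}

#: Average mass of one water molecule (terminal H and OH of a chain).
WATER_MASS: float = 18.01528

ROLES = ("alpha", "beta", "alpha_variant", "beta_variant", "linker")

#: Canonical ordering of roles inside a composition label.
_ROLE_ORDER = {
    "alpha_variant": 0,
    "alpha": 1,
    "beta_variant": 2,
    "beta": 3,
    "linker": 4,
}


def sequence_average_mass(sequence: str) -> float:
    """Average molecular mass of an unmodified polypeptide chain.

    Sum of residue average masses plus one water.  Raises ``ValueError``
    for an empty sequence or any non-canonical residue letter (the error
    message names the offending character and its 1-based position).
    """
    if not sequence:
        raise ValueError("empty sequence")
    total = WATER_MASS
    for pos, letter in enumerate(sequence, start=1):
        try:
            total += AVERAGE_RESIDUE_MASSES[letter]
        except KeyError:
            raise ValueError(
                f"unknown residue {letter!r} at position {pos}"
            ) from None
    return total


@dataclass(frozen=True)
class PtmRule:
    """A named mass adjustment applied ``count`` times to one subunit."""

    name: str
    delta_mass: float
    count: int = 1

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError(f"PTM {self.name!r}: count must be >= 0")
        if not (self.delta_mass == self.delta_mass and abs(self.delta_mass) < float("inf")):
            raise ValueError(f"PTM {self.name!r}: delta_mass must be finite")


@dataclass
class SubunitSpec:
    """A named polypeptide with either a sequence or a fixed mass.

    ``source`` groups subunits that come from the same organism/extract;
    ``family`` groups them into pigment-protein families.  Both default to
    empty strings, meaning "all the same group".
    """

    id: str
    role: str
    species: str = ""
    family: str = ""
    sequence: str | None = None
    fixed_mass: float | None = None
    ptms: tuple[PtmRule, ...] = ()

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"subunit {self.id!r}: unknown role {self.role!r}")
        if (self.sequence is None) == (self.fixed_mass is None):
            raise ValueError(
                f"subunit {self.id!r}: exactly one of sequence/fixed_mass must be set"
            )
        self.ptms = tuple(self.ptms)
        if resolve_subunit_mass(self) <= 0:
            raise ValueError(f"subunit {self.id!r}: resolved mass must be > 0")

    @property
    def source(self) -> str:
        return self.species


def resolve_subunit_mass(subunit: SubunitSpec) -> float:
    """PTM-adjusted average mass of one subunit.

    ``fixed_mass`` (if given) or the sequence mass, plus the sum of
    ``count * delta_mass`` over the attached PTM rules.
    """
    if subunit.fixed_mass is not None:
        base = float(subunit.fixed_mass)
    elif subunit.sequence is not None:
        base = sequence_average_mass(subunit.sequence)
    else:  # pragma: no cover - guarded by __post_init__
        raise ValueError(f"subunit {subunit.id!r}: no sequence or fixed_mass")
    return base + sum(rule.count * rule.delta_mass for rule in subunit.ptms)


@dataclass(frozen=True)
class ComplexComposition:
    """A multiset of subunits with a canonical label and a theoretical mass."""

    members: tuple[tuple[str, int], ...]
    label: str
    theoretical_mass: float

    @classmethod
    def from_members(
        cls,
        members: Mapping[str, int],
        registry: Mapping[str, SubunitSpec],
    ) -> "ComplexComposition":
        canon = _canonical_members(members, registry)
        return cls(
            members=canon,
            label=composition_label(members, registry),
            theoretical_mass=composition_mass(members, registry),
        )

    def copy_count(self) -> int:
        return sum(n for _, n in self.members)


def _canonical_members(
    members: Mapping[str, int], registry: Mapping[str, SubunitSpec]
) -> tuple[tuple[str, int], ...]:
    items = [(sid, n) for sid, n in members.items() if n > 0]
    if not items:
        raise ValueError("empty composition")
    for sid, _ in items:
        if sid not in registry:
            raise KeyError(f"unknown subunit id {sid!r}")
    items.sort(key=lambda kv: (_ROLE_ORDER[registry[kv[0]].role], kv[0]))
    return tuple(items)


def composition_label(
    members: Mapping[str, int], registry: Mapping[str, SubunitSpec]
) -> str:
    """Deterministic human-readable formula for a member multiset.

    Non-linker members are sorted by (role rank, id) and joined with ``.``,
    each written as ``<count><id>`` with the count omitted when 1; linker
    members are appended after ``+``.  E.g. ``"2aB.a.3b+Lc"``.
    """
    canon = _canonical_members(members, registry)
    core = [
        (sid, n) for sid, n in canon if registry[sid].role != "linker"
    ]
    linkers = [
        (sid, n) for sid, n in canon if registry[sid].role == "linker"
    ]

    def fmt(sid: str, n: int) -> str:
        return f"{n}{sid}" if n > 1 else sid

    label = ".".join(fmt(s, n) for s, n in core)
    for sid, n in linkers:
        label += "+" + fmt(sid, n)
    return label


def composition_mass(
    members: Mapping[str, int], registry: Mapping[str, SubunitSpec]
) -> float:
    """Sum of copy-number-weighted PTM-adjusted subunit masses."""
    canon = _canonical_members(members, registry)
    return sum(n * resolve_subunit_mass(registry[sid]) for sid, n in canon)


@dataclass
class AssemblyRules:
    """Configuration of which complex compositions are enumerated.

    A protomer is one (alpha-role, beta-role) subunit pair from the same
    source.  Oligomers are multisets of protomers; variant subunits then
    substitute their cognate base subunit up to a per-role cap, and linker
    subunits attach to the oligomer states listed in ``linker_attach_states``.

    ``allow_cross_family_protomers`` defaults to on so that the absence of
    cross-family complexes downstream is an empirical finding rather than a
    modelling assumption.  ``allow_cross_source_pairing`` additionally forms
    mixed protomers (alpha from one source, beta from another within the
    same family), which is needed to pose isoform-hybrid queries.
    """

    oligomer_states: frozenset[int] = frozenset({1, 3})
    max_variant_substitutions: dict[str, int] = field(
        default_factory=lambda: {"alpha_variant": 3, "beta_variant": 1}
    )
    linker_max_copies: int = 1
    linker_attach_states: frozenset[int] = frozenset({3})
    allow_cross_source_protomers: bool = False
    allow_cross_family_protomers: bool = True
    allow_cross_source_pairing: bool = False

    def __post_init__(self) -> None:
        self.oligomer_states = frozenset(int(n) for n in self.oligomer_states)
        self.linker_attach_states = frozenset(
            int(n) for n in self.linker_attach_states
        )
        if not self.oligomer_states:
            raise ValueError("oligomer_states must be non-empty")
        if any(n < 1 for n in self.oligomer_states):
            raise ValueError("oligomer states must be >= 1")
        if self.linker_max_copies < 0:
            raise ValueError("linker_max_copies must be >= 0")
        if any(v < 0 for v in self.max_variant_substitutions.values()):
            raise ValueError("variant substitution caps must be >= 0")


def _protomer_types(
    inventory: Sequence[SubunitSpec], rules: AssemblyRules
) -> list[tuple[SubunitSpec, SubunitSpec]]:
    alphas = [s for s in inventory if s.role == "alpha"]
    betas = [s for s in inventory if s.role == "beta"]
    pairs = []
    for a in alphas:
        for b in betas:
            if a.family != b.family:
                continue
            if a.source != b.source and not rules.allow_cross_source_pairing:
                continue
            pairs.append((a, b))
    pairs.sort(key=lambda ab: (ab[0].id, ab[1].id))
    return pairs


def _mixing_allowed(
    protomers: Sequence[tuple[SubunitSpec, SubunitSpec]], rules: AssemblyRules
) -> bool:
    families = {a.family for a, _ in protomers} | {b.family for _, b in protomers}
    if len(families) > 1 and not rules.allow_cross_family_protomers:
        return False
    # within-family source mixing
    for fam in families:
        sources = {
            s.source
            for a, b in protomers
            for s in (a, b)
            if s.family == fam
        }
        if len(sources) > 1 and not rules.allow_cross_source_protomers:
            return False
    return True


def enumerate_compositions(
    inventory: Sequence[SubunitSpec], rules: AssemblyRules
) -> list[ComplexComposition]:
    """All complex compositions permitted by the assembly rules.

    For each oligomer state *n*, every size-*n* multiset of protomer types
    allowed by the mixing flags is generated; variant subunits then replace
    their cognate base subunit (same source and family) in 0..cap copies,
    and each linker attaches in 0..``linker_max_copies`` copies to the
    states in ``linker_attach_states``.  Output is deduplicated by label
    and label-sorted, hence deterministic.
    """
    registry = {s.id: s for s in inventory}
    if len(registry) != len(inventory):
        raise ValueError("duplicate subunit ids in inventory")

    # every (family, source) group with core subunits needs an alpha and a beta
    groups: dict[tuple[str, str], set[str]] = {}
    for s in inventory:
        if s.role in ("alpha", "beta", "alpha_variant", "beta_variant"):
            groups.setdefault((s.family, s.source), set()).add(s.role)
    for (fam, src), roles in groups.items():
        base = roles & {"alpha", "beta"}
        if base != {"alpha", "beta"}:
            raise ValueError(
                f"source {src!r} (family {fam!r}) lacks an alpha or beta subunit"
            )

    protomers = _protomer_types(inventory, rules)
    variants = [s for s in inventory if s.role in ("alpha_variant", "beta_variant")]
    linkers = sorted(
        (s for s in inventory if s.role == "linker"), key=lambda s: s.id
    )

    out: dict[str, ComplexComposition] = {}
    for n in sorted(rules.oligomer_states):
        for combo in itertools.combinations_with_replacement(protomers, n):
            if not _mixing_allowed(combo, rules):
                continue
            base: dict[str, int] = {}
            for a, b in combo:
                base[a.id] = base.get(a.id, 0) + 1
                base[b.id] = base.get(b.id, 0) + 1
            for members in _variant_substitutions(base, variants, registry, rules):
                for final in _with_linkers(members, linkers, n, rules):
                    comp = ComplexComposition.from_members(final, registry)
                    out[comp.label] = comp
    return [out[k] for k in sorted(out)]


def _variant_substitutions(
    base: Mapping[str, int],
    variants: Sequence[SubunitSpec],
    registry: Mapping[str, SubunitSpec],
    rules: AssemblyRules,
) -> Iterable[dict[str, int]]:
    """Yield the base composition and every allowed variant-substituted one."""
    cognate_role = {"alpha_variant": "alpha", "beta_variant": "beta"}
    results = [dict(base)]
    for v in sorted(variants, key=lambda s: s.id):
        cap = rules.max_variant_substitutions.get(v.role, 0)
        targets = [
            sid
            for sid in base
            if registry[sid].role == cognate_role[v.role]
            and registry[sid].family == v.family
            and registry[sid].source == v.source
        ]
        if cap == 0 or not targets:
            continue
        expanded = []
        for members in results:
            expanded.append(members)
            for target in targets:
                avail = members.get(target, 0)
                for s in range(1, min(cap, avail) + 1):
                    sub = dict(members)
                    sub[target] = avail - s
                    if sub[target] == 0:
                        del sub[target]
                    sub[v.id] = sub.get(v.id, 0) + s
                    expanded.append(sub)
        results = expanded
    return results


def _with_linkers(
    members: Mapping[str, int],
    linkers: Sequence[SubunitSpec],
    oligomer_state: int,
    rules: AssemblyRules,
) -> Iterable[dict[str, int]]:
    results = [dict(members)]
    if oligomer_state not in rules.linker_attach_states:
        return results
    for linker in linkers:
        expanded = []
        for m in results:
            for copies in range(rules.linker_max_copies + 1):
                out = dict(m)
                if copies:
                    out[linker.id] = copies
                expanded.append(out)
        results = expanded
    return results


# ---------------------------------------------------------------------------
# file interfaces
# ---------------------------------------------------------------------------

def read_subunits_fasta(path: str | Path) -> list[SubunitSpec]:
    """Read subunits from FASTA; headers are ``id|species|role[|family]``."""
    from Bio import SeqIO

    subunits = []
    for record in SeqIO.parse(str(path), "fasta"):
        fields = record.description.split("|")
        if len(fields) < 3:
            raise ValueError(
                f"FASTA header {record.description!r}: expected 'id|species|role[|family]'"
            )
        sid, species, role = fields[0].strip(), fields[1].strip(), fields[2].strip()
        family = fields[3].strip() if len(fields) > 3 else ""
        subunits.append(
            SubunitSpec(
                id=sid,
                species=species,
                role=role,
                family=family,
                sequence=str(record.seq).upper(),
            )
        )
    return subunits


def write_subunits_fasta(subunits: Sequence[SubunitSpec], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in subunits:
            if s.sequence is None:
                raise ValueError(f"subunit {s.id!r} has no sequence to write")
            header = f"{s.id}|{s.species}|{s.role}"
            if s.family:
                header += f"|{s.family}"
            fh.write(f">{header}\n")
            for i in range(0, len(s.sequence), 60):
                fh.write(s.sequence[i : i + 60] + "\n")


def read_ptm_rules_tsv(path: str | Path) -> dict[str, list[PtmRule]]:
    """Read PTM rules; columns subunit_id, ptm_name, delta_mass, count."""
    rules: dict[str, list[PtmRule]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "subunit_id":  # header
                continue
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 tab-separated columns")
            sid, name, delta, count = parts
            rules.setdefault(sid, []).append(
                PtmRule(name=name, delta_mass=float(delta), count=int(count))
            )
    return rules


def attach_ptm_rules(
    subunits: Sequence[SubunitSpec], rules: Mapping[str, Sequence[PtmRule]]
) -> list[SubunitSpec]:
    """Return subunits with PTM rules attached by id (missing ids = no PTMs)."""
    out = []
    for s in subunits:
        out.append(
            SubunitSpec(
                id=s.id,
                species=s.species,
                role=s.role,
                family=s.family,
                sequence=s.sequence,
                fixed_mass=s.fixed_mass,
                ptms=tuple(rules.get(s.id, ())),
            )
        )
    return out


_RULE_PARSERS = {
    "oligomer_states": lambda v: frozenset(int(x) for x in str(v).split(",")),
    "linker_attach_states": lambda v: frozenset(int(x) for x in str(v).split(",")),
    "linker_max_copies": int,
    "allow_cross_source_protomers": lambda v: str(v).lower() in ("1", "true", "yes", "on"),
    "allow_cross_family_protomers": lambda v: str(v).lower() in ("1", "true", "yes", "on"),
    "allow_cross_source_pairing": lambda v: str(v).lower() in ("1", "true", "yes", "on"),
}


def read_assembly_rules(path: str | Path) -> AssemblyRules:
    """Read assembly rules from a flat ``key = value`` file.

    Variant caps are written as ``max_substitutions.<role> = <int>``.
    """
    kwargs: dict = {}
    caps: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (t.strip() for t in line.split("=", 1))
            if key.startswith("max_substitutions."):
                caps[key.split(".", 1)[1]] = int(value)
            elif key in _RULE_PARSERS:
                kwargs[key] = _RULE_PARSERS[key](value)
            else:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
    if caps:
        kwargs["max_variant_substitutions"] = caps
    return AssemblyRules(**kwargs)


def write_compositions_tsv(
    compositions: Sequence[ComplexComposition], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("label\tmembers\ttheoretical_mass\n")
        for c in compositions:
            members = ",".join(f"{sid}:{n}" for sid, n in c.members)
            fh.write(f"{c.label}\t{members}\t{c.theoretical_mass:.4f}\n")
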