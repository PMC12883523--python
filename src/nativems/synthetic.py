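"""Synthetic subunit inventories and native-ESI spectra with ground truth.

Everything here is seeded and deterministic so the whole pipeline can be
exercised end-to-end without instrument data.  Charge envelopes are
centred on the empirical native-ESI charging rule z = round(0.0778*sqrt(M))
and peaks are Gaussian at a configurable resolving power.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from . import _mzml
from .defaults import MZ_WINDOW, PROTON_MASS, RESOLUTION
from .mass_model import (
    AssemblyRules,
    ComplexComposition,
    PtmRule,
    SubunitSpec,
    enumerate_compositions,
    write_subunits_fasta,
)
from .spectrum_io import Spectrum

__all__ = [
    "PCB_MASS",
    "MET_LOSS_MASS",
    "METHYLATION_MASS",
    "SimScenario",
    "SpeciesTruth",
    "GroundTruth",
    "NamedScenario",
    "default_charge_center",
    "make_inventory",
    "simulate_spectrum",
    "scenario_library",
    "write_spectrum_xy",
    "write_spectrum_mzml",
]

#: Average-mass deltas of the modelled modifications.
PCB_MASS = 586.7
MET_LOSS_MASS = -131.2
METHYLATION_MASS = 14.0

# residue letters with roughly natural protein frequencies
_RESIDUES = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_FREQS = np.array(
    [8.3, 1.4, 5.4, 6.8, 3.9, 7.1, 2.3, 6.0, 5.8, 9.7,
     2.4, 4.1, 4.7, 3.9, 5.5, 6.6, 5.4, 6.9, 1.1, 2.9]
)
_FREQS = _FREQS / _FREQS.sum()

_PTMS_BY_ROLE = {
    "alpha": (PtmRule("PCB", PCB_MASS, 1), PtmRule("Met-loss", MET_LOSS_MASS, 1)),
    "alpha_variant": (PtmRule("PCB", PCB_MASS, 1), PtmRule("Met-loss", MET_LOSS_MASS, 1)),
    "beta": (PtmRule("PCB", PCB_MASS, 2), PtmRule("methylation", METHYLATION_MASS, 1)),
    "beta_variant": (PtmRule("PCB", PCB_MASS, 2), PtmRule("methylation", METHYLATION_MASS, 1)),
    "linker": (),
}


def default_charge_center(mass: float) -> int:
    """Empirical native-ESI mean charge: round(0.0778 * sqrt(M))."""
    return max(1, round(0.0778 * math.sqrt(mass)))


@dataclass
class SimScenario:
    """Species to simulate plus instrument/noise parameters."""

    species: list[tuple[ComplexComposition, float]]
    charge_center_rule: Callable[[float], int] = default_charge_center
    charge_envelope_width: float = 1.2
    resolution: float = RESOLUTION
    noise_sigma: float = 0.0
    mz_grid: tuple[float, float, float] = (*MZ_WINDOW, 0.02)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("scenario needs at least one species")
        abundances = [a for _, a in self.species]
        if any(not (0 < a <= 1) for a in abundances):
            raise ValueError("abundances must lie in (0, 1]")
        if max(abundances) != 1.0:
            raise ValueError("the most abundant species must have abundance 1")
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")


@dataclass
class SpeciesTruth:
    label: str
    neutral_mass: float
    abundance: float
    charges: list[int]
    apex_mz: list[float]
    apex_height: list[float]


@dataclass
class GroundTruth:
    species: list[SpeciesTruth]
    noise_sigma: float = 0.0
    baseline_offset: float = 0.0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "noise_sigma": self.noise_sigma,
            "baseline_offset": self.baseline_offset,
            "species": [
                {
                    "label": s.label,
                    "neutral_mass": s.neutral_mass,
                    "abundance": s.abundance,
                    "charges": s.charges,
                    "apex_mz": s.apex_mz,
                    "apex_height": s.apex_height,
                }
                for s in self.species
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_RESIDUES, size=length, p=_FREQS))


def make_inventory(
    seed: int,
    n_families: int = 1,
    variants_per_family: tuple[int, int] = (0, 0),
    length_range: tuple[int, int] = (150, 190),
    *,
    sources_per_family: int = 1,
    include_linker: bool = False,
    rules: AssemblyRules | None = None,
    min_subunit_gap: float = 0.003,
    min_composition_gap: float = 0.0025,
    fasta_path: str | Path | None = None,
) -> list[SubunitSpec]:
    """Seeded random subunit inventory with mass-resolvable members.

    Sequences use realistic residue frequencies; role-typical PTM rules
    are attached (1 bilin + Met loss on alpha roles, 2 bilins + methylation
    on beta roles, none on linkers).  Subunit masses are regenerated until
    all pairwise relative gaps are >= ``min_subunit_gap`` (default 0.3%)
    and — when ``rules`` is given — all enumerated composition masses
    differ pairwise by >= ``min_composition_gap``, so that assignment at
    the 0.1% threshold is unambiguous.  Raises after 1000 failed attempts.
    """
    if length_range[0] < 50:
        raise ValueError("sequence lengths must be >= 50")
    if length_range[0] > length_range[1]:
        raise ValueError("invalid length_range")
    n_av, n_bv = variants_per_family
    rng = np.random.default_rng(seed)

    blueprint: list[tuple[str, str, str, str]] = []  # id, role, source, family
    for f in range(1, n_families + 1):
        fam = f"F{f}"
        for s in range(1, sources_per_family + 1):
            src = f"{fam}s{s}"
            blueprint.append((f"a{f}{s}", "alpha", src, fam))
            blueprint.append((f"b{f}{s}", "beta", src, fam))
            for v in range(n_av):
                blueprint.append((f"aV{f}{s}{v + 1}", "alpha_variant", src, fam))
            for v in range(n_bv):
                blueprint.append((f"bV{f}{s}{v + 1}", "beta_variant", src, fam))
        if include_linker:
            # short linker, no PTMs, attaches to trimers
            blueprint.append((f"L{f}", "linker", f"{fam}s1", fam))

    for attempt in range(1000):
        subunits: list[SubunitSpec] = []
        for sid, role, src, fam in blueprint:
            length = (
                int(rng.integers(60, 75))
                if role == "linker"
                else int(rng.integers(length_range[0], length_range[1] + 1))
            )
            subunits.append(
                SubunitSpec(
                    id=sid,
                    role=role,
                    species=src,
                    family=fam,
                    sequence=_random_sequence(rng, length),
                    ptms=_PTMS_BY_ROLE[role],
                )
            )
        if _inventory_resolvable(subunits, rules, min_subunit_gap, min_composition_gap):
            if fasta_path is not None:
                write_subunits_fasta(subunits, fasta_path)
            return subunits
    raise RuntimeError(
        "could not satisfy mass-separation constraints after 1000 attempts"
    )


def _inventory_resolvable(
    subunits: Sequence[SubunitSpec],
    rules: AssemblyRules | None,
    min_subunit_gap: float,
    min_composition_gap: float,
) -> bool:
    from .mass_model import resolve_subunit_mass

    masses = sorted(resolve_subunit_mass(s) for s in subunits)
    for lo, hi in zip(masses, masses[1:]):
        if (hi - lo) / hi < min_subunit_gap:
            return False
    if rules is not None:
        cmasses = sorted(
            c.theoretical_mass for c in enumerate_compositions(list(subunits), rules)
        )
        for lo, hi in zip(cmasses, cmasses[1:]):
            if (hi - lo) / hi < min_composition_gap:
                return False
    return True


def simulate_spectrum(scenario: SimScenario) -> tuple[Spectrum, GroundTruth]:
    """Render a scenario into a profile spectrum plus its ground truth.

    Each species contributes Gaussian peaks at charges z_c - 3 .. z_c + 3
    (z_c from ``charge_center_rule``), heights proportional to abundance
    times a Gaussian charge weight, FWHM = m/z / resolution.  With
    ``noise_sigma > 0`` a constant offset of 6 sigma plus i.i.d. Gaussian
    noise is added (then clipped at zero), so an S/N cut against the
    MAD-estimated noise is meaningful.  The tallest planted apex has
    height 100 * abundance.
    """
    low, high, step = scenario.mz_grid
    grid = np.arange(low, high, step)
    signal = np.zeros_like(grid)
    truths: list[SpeciesTruth] = []

    for comp, abundance in scenario.species:
        mass = comp.theoretical_mass
        zc = scenario.charge_center_rule(mass)
        charges, apex_mz, apex_h = [], [], []
        for z in range(max(1, zc - 3), zc + 4):
            weight = math.exp(
                -((z - zc) ** 2) / (2 * scenario.charge_envelope_width**2)
            )
            center = (mass + z * PROTON_MASS) / z
            if not (low <= center < high):
                warnings.warn(
                    f"{comp.label}: charge {z} peak at {center:.1f} m/z is "
                    "outside the grid; truncated"
                )
                continue
            height = 100.0 * abundance * weight
            sigma = center / scenario.resolution / 2.3548200450309493
            lo = int(np.searchsorted(grid, center - 6 * sigma))
            hi = int(np.searchsorted(grid, center + 6 * sigma))
            window = grid[lo:hi]
            signal[lo:hi] += height * np.exp(
                -((window - center) ** 2) / (2 * sigma**2)
            )
            charges.append(z)
            apex_mz.append(center)
            apex_h.append(height)
        truths.append(
            SpeciesTruth(
                label=comp.label,
                neutral_mass=mass,
                abundance=abundance,
                charges=charges,
                apex_mz=apex_mz,
                apex_height=apex_h,
            )
        )

    offset = 0.0
    if scenario.noise_sigma > 0:
        rng = np.random.default_rng(scenario.seed)
        offset = 6.0 * scenario.noise_sigma
        signal = signal + offset + rng.normal(0.0, scenario.noise_sigma, len(grid))
        signal = np.clip(signal, 0.0, None)

    spectrum = Spectrum(mz=grid, intensity=signal, window=(low, high))
    return spectrum, GroundTruth(
        species=truths, noise_sigma=scenario.noise_sigma, baseline_offset=offset
    )


@dataclass
class NamedScenario:
    """A canned scenario bundled with everything the pipeline needs."""

    name: str
    description: str
    inventory: list[SubunitSpec]
    rules: AssemblyRules
    scenario: SimScenario
    #: labels planted in the spectrum
    planted: list[str]
    #: labels to interrogate downstream (hybrid presence/absence)
    queries: list[str]


def _by_label(comps: Sequence[ComplexComposition]) -> dict[str, ComplexComposition]:
    return {c.label: c for c in comps}


def scenario_library(noise_sigma: float = 0.15, seed: int = 0) -> dict[str, NamedScenario]:
    """Canned scenarios mirroring the published figure inventories.

    - ``fig1b``: core trimer with and without a small linker (3% abundance)
    - ``fig1c``: dominant dimer from one family plus minor dimers,
      including a beta-variant-substituted one
    - ``fig1d``: trimers carrying 0-3 copies of an alpha variant
    - ``fig2``: two families that do not mix; hybrid queries planted absent
    - ``fig3``: two same-family isoform sources; cross-paired dimer queries
      planted absent
    - ``fig4e``: two same-family sources with a planted cross-source hybrid
      trimer
    """
    lib: dict[str, NamedScenario] = {}

    def scenario(comps_abund, rules, inv, name, desc, queries, seed_off=0):
        comps = [c for c, _ in comps_abund]
        lib[name] = NamedScenario(
            name=name,
            description=desc,
            inventory=inv,
            rules=rules,
            scenario=SimScenario(
                species=comps_abund, noise_sigma=noise_sigma, seed=seed + seed_off
            ),
            planted=[c.label for c in comps],
            queries=queries,
        )

    # -- fig1b: trimer +/- linker ------------------------------------------
    rules_1b = AssemblyRules(oligomer_states=frozenset({3}))
    inv_1b = make_inventory(11, include_linker=True, rules=rules_1b)
    cands = _by_label(enumerate_compositions(inv_1b, rules_1b))
    labels = sorted(cands)
    plain = [l for l in labels if "+" not in l][0]
    with_linker = [l for l in labels if "+" in l][0]
    scenario(
        [(cands[plain], 1.0), (cands[with_linker], 0.03)],
        rules_1b, inv_1b, "fig1b",
        "core trimer with a 3%-abundance linker-bound form",
        queries=[plain, with_linker], seed_off=1,
    )

    # -- fig1c: dimer mixture with a beta-variant dimer --------------------
    rules_1c = AssemblyRules(
        oligomer_states=frozenset({1}),
        max_variant_substitutions={"alpha_variant": 0, "beta_variant": 1},
    )
    inv_1c = make_inventory(12, n_families=2, variants_per_family=(0, 1), rules=rules_1c)
    cands = _by_label(enumerate_compositions(inv_1c, rules_1c))
    base_f1 = [l for l in sorted(cands) if l.startswith("a1") and "bV" not in l][0]
    var_f1 = [l for l in sorted(cands) if l.startswith("a1") and "bV" in l][0]
    base_f2 = [l for l in sorted(cands) if l.startswith("a2") and "bV" not in l][0]
    scenario(
        [(cands[base_f2], 1.0), (cands[base_f1], 0.15), (cands[var_f1], 0.08)],
        rules_1c, inv_1c, "fig1c",
        "dominant dimer plus minor dimers incl. a beta-variant form",
        queries=[base_f1, var_f1], seed_off=2,
    )

    # -- fig1d: 0-3 alpha-variant substitutions ----------------------------
    rules_1d = AssemblyRules(oligomer_states=frozenset({3}))
    inv_1d = make_inventory(13, variants_per_family=(1, 0), rules=rules_1d)
    cands = _by_label(enumerate_compositions(inv_1d, rules_1d))
    ordered = sorted(cands.values(), key=lambda c: sum(
        n for sid, n in c.members if sid.startswith("aV")
    ))
    abunds = [1.0, 0.6, 0.3, 0.1]
    scenario(
        list(zip(ordered, abunds)),
        rules_1d, inv_1d, "fig1d",
        "trimers carrying 0-3 copies of an alpha variant",
        queries=[c.label for c in ordered], seed_off=3,
    )

    # -- fig2: two families, no hybrids planted ----------------------------
    rules_2 = AssemblyRules(oligomer_states=frozenset({3}))
    inv_2 = make_inventory(14, n_families=2, rules=rules_2)
    cands = _by_label(enumerate_compositions(inv_2, rules_2))
    pure_f1 = [l for l in sorted(cands) if all(sid[1] == "1" for sid, _ in cands[l].members)][0]
    pure_f2 = [l for l in sorted(cands) if all(sid[1] == "2" for sid, _ in cands[l].members)][0]
    hybrids = [l for l in sorted(cands) if l not in (pure_f1, pure_f2)]
    scenario(
        [(cands[pure_f1], 1.0), (cands[pure_f2], 0.8)],
        rules_2, inv_2, "fig2",
        "two pure-family trimers; cross-family hybrids queried but absent",
        queries=hybrids, seed_off=4,
    )

    # -- fig3: isoform sources, cross-paired dimers absent -----------------
    rules_3 = AssemblyRules(
        oligomer_states=frozenset({1, 3}),
        allow_cross_source_pairing=True,
        allow_cross_source_protomers=True,
    )
    inv_3 = make_inventory(16, sources_per_family=2, rules=rules_3)
    cands = _by_label(enumerate_compositions(inv_3, rules_3))
    d11, d22 = "a11.b11", "a12.b12"
    t11 = [l for l in sorted(cands) if l == "3a11.3b11"][0]
    t22 = [l for l in sorted(cands) if l == "3a12.3b12"][0]
    cross_dimers = ["a11.b12", "a12.b11"]
    scenario(
        [(cands[d11], 1.0), (cands[d22], 0.7), (cands[t11], 0.5), (cands[t22], 0.35)],
        rules_3, inv_3, "fig3",
        "pure isoform dimers/trimers; cross-paired dimers queried but absent",
        queries=cross_dimers, seed_off=5,
    )

    # -- fig4e: cross-source hybrid trimer planted -------------------------
    rules_4 = AssemblyRules(
        oligomer_states=frozenset({3}), allow_cross_source_protomers=True
    )
    inv_4 = make_inventory(17, sources_per_family=2, rules=rules_4)
    cands = _by_label(enumerate_compositions(inv_4, rules_4))
    pure_1, pure_2 = "3a11.3b11", "3a12.3b12"
    hybrid_21 = "2a11.a12.2b11.b12"  # 2 protomers of source 1 + 1 of source 2
    hybrid_12 = "a11.2a12.b11.2b12"
    scenario(
        [
            (cands[pure_1], 1.0),
            (cands[pure_2], 0.75),
            (cands[hybrid_21], 0.2),
            (cands[hybrid_12], 0.15),
        ],
        rules_4, inv_4, "fig4e",
        "two sources of one family with planted cross-source hybrid trimers",
        queries=[hybrid_21, hybrid_12], seed_off=6,
    )

    return lib


def write_spectrum_xy(spectrum: Spectrum, path: str | Path) -> None:
    np.savetxt(
        path,
        np.column_stack([spectrum.mz, spectrum.intensity]),
        fmt="%.6f %.6f",
    )


def write_spectrum_mzml(spectrum: Spectrum, path: str | Path) -> None:
    _mzml.write_mzml(path, [(spectrum.mz, spectrum.intensity)])
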