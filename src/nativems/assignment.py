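"""Match experimental masses to enumerated compositions and issue
presence/absence verdicts for queried heterogeneous complexes.

A series is assigned to a composition when the percent mass error
100*|M_exp - M_theo|/M_theo is strictly below the threshold (default 0.1%).
A "not_detected" verdict means no series fell within threshold — it does
not assert absence below the noise level.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import defaults
from .deconvolution import (
    ChargeSeries,
    DeconvParams,
    find_series,
    mz_from_mass,
    write_series_tsv,
)
from .mass_model import (
    ComplexComposition,
    attach_ptm_rules,
    enumerate_compositions,
    read_assembly_rules,
    read_ptm_rules_tsv,
    read_subunits_fasta,
    write_compositions_tsv,
)
from .spectrum_io import pick_peaks, read_spectrum, write_peaks_tsv

__all__ = [
    "Assignment",
    "Verdict",
    "HeterogeneityReport",
    "PipelineError",
    "match",
    "unassigned_series",
    "classify_abundance",
    "heterogeneity_verdict",
    "run_pipeline",
]


@dataclass
class Assignment:
    series: ChargeSeries
    composition: ComplexComposition
    pct_error: float
    is_primary: bool = False
    ambiguous: bool = False
    abundance_class: str | None = None


def match(
    series_list: Sequence[ChargeSeries],
    candidates: Sequence[ComplexComposition],
    max_pct_error: float = defaults.MAX_PCT_ERROR,
) -> list[Assignment]:
    """All (series, composition) pairs with percent error < threshold.

    For each series every in-range candidate is reported, ranked by
    |pct_error|; the best match is flagged primary, and if more than one
    candidate is in range all of them are flagged ambiguous.
    """
    assignments: list[Assignment] = []
    for series in series_list:
        in_range = []
        for comp in candidates:
            if comp.theoretical_mass is None:
                raise ValueError(f"candidate {comp.label!r} has no theoretical mass")
            pct = 100.0 * abs(series.neutral_mass - comp.theoretical_mass) / comp.theoretical_mass
            if pct < max_pct_error:
                in_range.append(Assignment(series=series, composition=comp, pct_error=pct))
        in_range.sort(key=lambda a: a.pct_error)
        if in_range:
            in_range[0].is_primary = True
            if len(in_range) > 1:
                for a in in_range:
                    a.ambiguous = True
        assignments.extend(in_range)
    return assignments


def unassigned_series(
    series_list: Sequence[ChargeSeries], assignments: Sequence[Assignment]
) -> list[ChargeSeries]:
    matched = {id(a.series) for a in assignments}
    return [s for s in series_list if id(s) not in matched]


def classify_abundance(
    assignment: Assignment,
    low_abundance_frac: float = defaults.LOW_ABUNDANCE_FRAC,
) -> str:
    """"low_abundant" iff the series relative intensity is strictly below
    the cutoff fraction of the base series, else "major"."""
    cls = (
        "low_abundant"
        if assignment.series.relative_intensity < low_abundance_frac
        else "major"
    )
    assignment.abundance_class = cls
    return cls


@dataclass
class Verdict:
    query: str
    status: str  # detected | ambiguous-detected | not_detected
    assignment: Assignment | None = None
    #: expected (z, m/z) ladder for inspection when not detected
    expected_mz_ladder: list[tuple[int, float]] = field(default_factory=list)
    #: percent error of the nearest-mass observed series, if any
    nearest_series_pct_error: float | None = None


@dataclass
class HeterogeneityReport:
    verdicts: dict[str, Verdict]
    max_pct_error: float = defaults.MAX_PCT_ERROR
    low_abundance_frac: float = defaults.LOW_ABUNDANCE_FRAC
    sn_threshold: float = defaults.SN_THRESHOLD


def heterogeneity_verdict(
    assignments: Sequence[Assignment],
    unassigned: Sequence[ChargeSeries],
    queries: Sequence[str],
    candidates: Sequence[ComplexComposition],
    max_pct_error: float = defaults.MAX_PCT_ERROR,
    low_abundance_frac: float = defaults.LOW_ABUNDANCE_FRAC,
    sn_threshold: float = defaults.SN_THRESHOLD,
) -> HeterogeneityReport:
    """Presence/absence verdict for each queried composition label.

    A query is *detected* when it is the primary composition of some
    assignment (*ambiguous-detected* when that assignment had several
    candidates within threshold — the data cannot tell them apart).
    Otherwise it is *not_detected*, with the theoretical m/z ladder over
    the observed charge range and the nearest series' percent error as
    evidence.
    """
    by_label = {c.label: c for c in candidates}
    for q in queries:
        if q not in by_label:
            raise KeyError(f"query {q!r} is not an enumerated candidate label")

    all_series = [a.series for a in assignments] + list(unassigned)
    observed_charges = sorted({z for s in all_series for z in s.charges})
    if observed_charges:
        z_lo, z_hi = observed_charges[0], observed_charges[-1]
    else:
        z_lo, z_hi = 15, 30

    primaries = {a.composition.label: a for a in assignments if a.is_primary}
    verdicts: dict[str, Verdict] = {}
    for q in queries:
        comp = by_label[q]
        if q in primaries:
            a = primaries[q]
            classify_abundance(a, low_abundance_frac)
            status = "ambiguous-detected" if a.ambiguous else "detected"
            verdicts[q] = Verdict(query=q, status=status, assignment=a)
        else:
            ladder = [
                (z, mz_from_mass(comp.theoretical_mass, z))
                for z in range(z_lo, z_hi + 1)
            ]
            nearest = None
            if all_series:
                best = min(
                    all_series,
                    key=lambda s: abs(s.neutral_mass - comp.theoretical_mass),
                )
                nearest = (
                    100.0
                    * abs(best.neutral_mass - comp.theoretical_mass)
                    / comp.theoretical_mass
                )
            verdicts[q] = Verdict(
                query=q,
                status="not_detected",
                expected_mz_ladder=ladder,
                nearest_series_pct_error=nearest,
            )
    return HeterogeneityReport(
        verdicts=verdicts,
        max_pct_error=max_pct_error,
        low_abundance_frac=low_abundance_frac,
        sn_threshold=sn_threshold,
    )


class PipelineError(RuntimeError):
    """An error raised by one pipeline stage, labelled with the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc

        return wrapped

    return deco


def run_pipeline(config: Mapping | str | Path, log=None) -> dict:
    """Execute read -> pick -> deconvolve -> enumerate -> match -> verdict.

    ``config`` is a mapping (or path to a YAML file) with keys:

    - ``fasta``: subunit FASTA (headers ``id|species|role[|family]``)
    - ``ptms``: PTM rule TSV (optional)
    - ``rules``: assembly-rules key=value file (optional -> defaults)
    - ``spectrum``: spectrum path; ``format``: ``mzml``/``xy_text`` (optional)
    - ``queries``: list of composition labels to test (optional)
    - ``out_dir``: output directory
    - thresholds: ``max_pct_error``, ``low_abundance_frac``, ``sn_threshold``
    - deconvolution: ``z_min``, ``z_max``, ``min_series_length``

    Writes ``compositions.tsv``, ``peaks.tsv``, ``series.tsv``,
    ``assignments.tsv`` and ``verdicts.tsv`` under ``out_dir`` and returns
    the in-memory results.  A no-detection verdict is a successful run.
    """
    log = log or (lambda msg: print(msg, file=sys.stderr))
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = dict(config)

    out_dir = Path(cfg.get("out_dir", "."))
    out_dir.mkdir(parents=True, exist_ok=True)
    max_pct_error = float(cfg.get("max_pct_error", defaults.MAX_PCT_ERROR))
    low_abund = float(cfg.get("low_abundance_frac", defaults.LOW_ABUNDANCE_FRAC))
    sn = float(cfg.get("sn_threshold", defaults.SN_THRESHOLD))
    log(
        f"thresholds: max_pct_error={max_pct_error}% "
        f"low_abundance_frac={low_abund} sn_threshold={sn}"
    )

    @_stage("inventory")
    def load_inventory():
        if "fasta" not in cfg:
            raise ValueError("config missing 'fasta'")
        subunits = read_subunits_fasta(cfg["fasta"])
        if "ptms" in cfg:
            subunits = attach_ptm_rules(subunits, read_ptm_rules_tsv(cfg["ptms"]))
        return subunits

    @_stage("assembly-rules")
    def load_rules():
        from .mass_model import AssemblyRules

        return read_assembly_rules(cfg["rules"]) if "rules" in cfg else AssemblyRules()

    @_stage("enumerate")
    def enumerate_(subunits, rules):
        comps = enumerate_compositions(subunits, rules)
        write_compositions_tsv(comps, out_dir / "compositions.tsv")
        return comps

    @_stage("spectrum")
    def load_spectrum():
        if "spectrum" not in cfg:
            raise ValueError("config missing 'spectrum'")
        return read_spectrum(cfg["spectrum"], format=cfg.get("format"))

    @_stage("peaks")
    def pick(spectrum):
        peaks = pick_peaks(spectrum, sn_threshold=sn)
        write_peaks_tsv(peaks, out_dir / "peaks.tsv")
        return peaks

    @_stage("deconvolve")
    def deconvolve(peaks):
        params = DeconvParams(
            z_range=(int(cfg.get("z_min", 5)), int(cfg.get("z_max", 40))),
            min_series_length=int(cfg.get("min_series_length", 3)),
        )
        series = find_series(peaks, params)
        write_series_tsv(series, out_dir / "series.tsv")
        return series

    subunits = load_inventory()
    rules = load_rules()
    candidates = enumerate_(subunits, rules)
    spectrum = load_spectrum()
    peaks = pick(spectrum)
    if not peaks:
        log("warning: no peaks above S/N threshold; reports will be empty")
    series = deconvolve(peaks)

    assignments = match(series, candidates, max_pct_error)
    for a in assignments:
        classify_abundance(a, low_abund)
    leftovers = unassigned_series(series, assignments)
    _write_assignments_tsv(assignments, leftovers, out_dir / "assignments.tsv")

    queries = list(cfg.get("queries", []))
    report = None
    if queries:
        report = heterogeneity_verdict(
            assignments, leftovers, queries, candidates,
            max_pct_error, low_abund, sn,
        )
        _write_verdicts_tsv(report, out_dir / "verdicts.tsv")
        for q, v in report.verdicts.items():
            log(f"verdict: {q} -> {v.status}")

    return {
        "candidates": candidates,
        "peaks": peaks,
        "series": series,
        "assignments": assignments,
        "unassigned": leftovers,
        "report": report,
    }


def _write_assignments_tsv(assignments, leftovers, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "neutral_mass\tlabel\ttheoretical_mass\tpct_error\tprimary\t"
            "ambiguous\tabundance_class\n"
        )
        for a in assignments:
            fh.write(
                f"{a.series.neutral_mass:.3f}\t{a.composition.label}\t"
                f"{a.composition.theoretical_mass:.3f}\t{a.pct_error:.5f}\t"
                f"{int(a.is_primary)}\t{int(a.ambiguous)}\t{a.abundance_class or ''}\n"
            )
        for s in leftovers:
            fh.write(f"{s.neutral_mass:.3f}\tUNASSIGNED\t\t\t\t\t\n")


def _write_verdicts_tsv(report: HeterogeneityReport, path) -> None:
    with open(path, "w") as fh:
        fh.write("query\tstatus\tpct_error\texpected_mz_21+\tnote\n")
        for q, v in report.verdicts.items():
            if v.status in ("detected", "ambiguous-detected"):
                fh.write(
                    f"{q}\t{v.status}\t{v.assignment.pct_error:.5f}\t\t"
                    f"class={v.assignment.abundance_class}\n"
                )
            else:
                ladder = dict(v.expected_mz_ladder)
                mz21 = ladder.get(21, next(iter(ladder.values()), float("nan")))
                err = (
                    f"{v.nearest_series_pct_error:.5f}"
                    if v.nearest_series_pct_error is not None
                    else ""
                )
                fh.write(
                    f"{q}\tnot_detected\t{err}\t{mz21:.3f}\t"
                    "no series within threshold; absence below noise not asserted\n"
                )
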