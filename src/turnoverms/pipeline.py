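"""End-to-end orchestration: mzML + identifications -> rate tables.

``run_quantify`` drives the full chain for a labeling time course:
index each run's MS1 scans, align retention times to the unlabeled
(day 0) reference and transfer missing identifications between runs
(MBR), extract and integrate isotopomer XICs, turn each peptide's
profile series into monoisotopic RIAs (complete-profile or two-
isotopomer ratio), fit the turnover rate, and write one
``<Protein>.RateConst.csv`` per protein plus the default-filtered
``Analyzed_Proteins_and_Their_Rates.csv``.

``run_refilter`` re-aggregates existing RateConst tables under
user-chosen quality thresholds.
"""

from __future__ import annotations

import logging
import math
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import extraction, filtering, rt_alignment
from .extraction import Identification, SpectrumIndex
from .filtering import (
    FilterCriteria,
    PeptideRateRecord,
    aggregate_protein,
    custom_filter,
    default_filter,
    read_rateconst_csv,
    write_protein_summary,
    write_rateconst_csv,
)
from .isotope_model import (
    EnrichmentModel,
    PeptideSpec,
    isotope_deviation,
    labeled_pattern,
    natural_isotope_pattern,
    ria_from_complete_profile,
    ria_from_isotopomer_ratio,
)
from .kinetics import (
    FitResult,
    PeptideTimeCourse,
    QuantSource,
    TimePoint,
    fit_one_parameter,
    fit_two_parameter,
)

logger = logging.getLogger("turnoverms")

__all__ = ["RunEntry", "RunManifest", "run_quantify", "run_refilter"]


@dataclass
class RunEntry:
    time: float  # labeling duration, days
    mzml: str
    ids: str
    run_id: str = ""

    def __post_init__(self) -> None:
        if not self.run_id:
            self.run_id = Path(self.mzml).stem


@dataclass
class RunManifest:
    """Configuration of one quantification job."""

    runs: list[RunEntry]
    pW: float
    fit_model: str = "one_parameter"  # or "two_parameter"
    ria_source: str = "complete"  # or "ratio:i,j"
    align: bool = True
    segment_len: int = rt_alignment.DEFAULT_SEGMENT_LEN
    slack: int = rt_alignment.DEFAULT_SLACK
    ppm_tol: float = extraction.DEFAULT_PPM_TOL
    rt_window: float = extraction.DEFAULT_RT_WINDOW
    rt_tol: float = rt_alignment.DEFAULT_RT_TOL
    criteria: FilterCriteria = field(default_factory=FilterCriteria)

    def __post_init__(self) -> None:
        self.runs = sorted(self.runs, key=lambda r: r.time)
        times = [r.time for r in self.runs]
        if len(set(times)) != len(times):
            raise ValueError("labeling time points must be unique")
        if not any(t == 0 for t in times):
            raise ValueError(
                "manifest must include a day-0 (unlabeled) run: the "
                "natural isotope profile anchors every fit"
            )
        if self.fit_model not in ("one_parameter", "two_parameter"):
            raise ValueError(f"unknown fit model: {self.fit_model}")
        self.ria_pair = _parse_ria_source(self.ria_source)

    @classmethod
    def from_toml(cls, path) -> "RunManifest":
        path = Path(path)
        with open(path, "rb") as fh:
            doc = tomllib.load(fh)
        base = path.parent
        runs = [
            RunEntry(
                time=float(r["time"]),
                mzml=str(base / r["mzml"]),
                ids=str(base / r["ids"]),
                run_id=r.get("run_id", ""),
            )
            for r in doc["runs"]
        ]
        align = doc.get("alignment", {})
        crit = doc.get("filter", {})
        return cls(
            runs=runs,
            pW=float(doc["pW"]),
            fit_model=doc.get("fit_model", "one_parameter"),
            ria_source=doc.get("ria_source", "complete"),
            align=bool(align.get("enabled", True)),
            segment_len=int(align.get("segment_len", rt_alignment.DEFAULT_SEGMENT_LEN)),
            slack=int(align.get("slack", rt_alignment.DEFAULT_SLACK)),
            ppm_tol=float(align.get("ppm_tol", extraction.DEFAULT_PPM_TOL)),
            rt_window=float(align.get("rt_window", extraction.DEFAULT_RT_WINDOW)),
            rt_tol=float(align.get("rt_tol", rt_alignment.DEFAULT_RT_TOL)),
            criteria=FilterCriteria(**{k: v for k, v in crit.items()}),
        )


def _parse_ria_source(source: str) -> tuple[int, int] | None:
    if source == "complete":
        return None
    if source.startswith("ratio:"):
        i, j = (int(x) for x in source[len("ratio:"):].split(","))
        return (i, j)
    raise ValueError(f"unknown RIA source: {source!r}")


def _peptide_window_bpc(
    index: SpectrumIndex, rt_center: float, rt_window: float, run_id: str
) -> rt_alignment.Chromatogram | None:
    """Base-peak chromatogram of a run restricted to an elution window."""
    scan_idx = list(index.scan_slice(rt_center - rt_window, rt_center + rt_window))
    if len(scan_idx) < 4:
        return None
    rts = index.rts[scan_idx]
    bpc = np.array(
        [
            index.intensity_arrays[s].max() if index.intensity_arrays[s].size else 0.0
            for s in scan_idx
        ]
    )
    return rt_alignment.Chromatogram(rt=rts, intensity=bpc, run_id=run_id)


def _compute_ria(
    raw: np.ndarray,
    pair: tuple[int, int] | None,
    natural: np.ndarray,
    labeled: np.ndarray,
) -> float:
    if pair is None:
        return ria_from_complete_profile(raw)
    i, j = pair
    if raw[j] <= 0:
        raise ValueError("zero denominator isotopomer")
    return ria_from_isotopomer_ratio(raw[i] / raw[j], i, j, natural, labeled)


def run_quantify(manifest: RunManifest, out_dir) -> dict:
    """Quantify turnover rates for every identified peptide and protein.

    Returns a dict with the per-protein record lists, fit results and
    output paths.  Outputs are deterministic for fixed inputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    enrichment = EnrichmentModel(pW=manifest.pW)

    indexes: dict[str, SpectrumIndex] = {}
    idents_by_run: dict[str, list[Identification]] = {}
    run_time: dict[str, float] = {}
    for entry in manifest.runs:
        try:
            indexes[entry.run_id] = extraction.read_mzml(entry.mzml, entry.run_id)
            idents_by_run[entry.run_id] = extraction.read_identifications_tsv(
                entry.ids, entry.run_id
            )
            run_time[entry.run_id] = entry.time
        except (OSError, ValueError) as exc:
            logger.warning("skipping run %s: %s", entry.run_id, exc)
    if not indexes:
        raise ValueError("no readable runs in manifest")
    day0_id = next(r.run_id for r in manifest.runs if r.time == 0)
    if day0_id not in indexes:
        raise ValueError("day-0 run could not be read")

    # one identification per (sequence, charge, run): keep the first
    peptides: dict[tuple[str, int], dict[str, Identification]] = {}
    for run_id, idents in idents_by_run.items():
        for ident in idents:
            entry = peptides.setdefault((ident.sequence, ident.charge), {})
            entry.setdefault(run_id, ident)

    run_ids = [r.run_id for r in manifest.runs if r.run_id in indexes]
    records_by_protein: dict[str, list[PeptideRateRecord]] = {}
    fits: dict[tuple[str, int], FitResult] = {}
    courses: dict[tuple[str, int], PeptideTimeCourse] = {}

    for key in sorted(peptides):
        sequence, charge = key
        by_run = peptides[key]
        try:
            spec = PeptideSpec(sequence=sequence, charge=charge)
        except ValueError as exc:
            logger.warning("skipping peptide %s/%d: %s", sequence, charge, exc)
            continue
        natural = natural_isotope_pattern(spec)
        labeled = labeled_pattern(natural, spec.neh, enrichment.excess_fraction)
        anchor = next(iter(by_run.values()))
        mz = anchor.mz
        proteins = anchor.proteins or ["UNASSIGNED"]

        points: list[TimePoint] = []
        abundances: list[float] = []
        iso_dev = math.nan
        for run_id in run_ids:
            index = indexes[run_id]
            ident = by_run.get(run_id)
            source = QuantSource.IDENTIFIED
            rt_center = None
            if ident is None:
                if not manifest.align:
                    continue
                rt_center = _transfer_rt(
                    key, by_run, index, indexes, manifest, mz, run_id
                )
                if rt_center is None:
                    continue
                ident = Identification(
                    sequence=sequence, charge=charge, mz=mz,
                    rt=rt_center, run_id=run_id,
                )
                source = QuantSource.MBR_TRANSFERRED
            xics = extraction.extract_isotopomer_xics(
                index, ident,
                ppm_tol=manifest.ppm_tol, rt_window=manifest.rt_window,
                rt_center=rt_center,
            )
            result = extraction.integrate_profile(xics) if xics else None
            if result is None:
                continue
            raw, avg_m0 = result
            try:
                ria = _compute_ria(raw, manifest.ria_pair, natural, labeled)
            except ValueError as exc:
                logger.debug("RIA failed %s/%d in %s: %s", sequence, charge, run_id, exc)
                continue
            if not (0.0 < ria <= 1.0):
                continue
            t = run_time[run_id]
            points.append(TimePoint(t=t, I0=ria, raw=raw, quant_source=source))
            abundances.append(avg_m0)
            if t == 0:
                iso_dev = isotope_deviation(raw, natural)

        if manifest.ria_pair is None:
            day0_points = [p for p in points if p.t == 0]
            I0_natural = (
                day0_points[0].I0 if day0_points else ria_from_complete_profile(natural)
            )
        else:
            # the ratio estimator is calibrated on theoretical patterns
            I0_natural = ria_from_complete_profile(natural)
        min_ndp = 3 if manifest.fit_model == "one_parameter" else 4
        if len(points) < min_ndp:
            logger.debug("too few points for %s/%d", sequence, charge)
            continue
        tc = PeptideTimeCourse(
            spec=spec,
            points=points,
            I0_natural=I0_natural,
            average_monoisotope_abundance=float(np.mean(abundances)),
        )
        try:
            if manifest.fit_model == "one_parameter":
                # the six-peak plateau RIA of the labeled pattern is the
                # theoretical asymptote consistent with the Eq-(2)-style
                # six-peak RIA normalization used on the data
                plateau = ria_from_complete_profile(labeled) * (
                    I0_natural / ria_from_complete_profile(natural)
                )
                fit = fit_one_parameter(tc, enrichment, I0_asymp=plateau)
            else:
                fit = fit_two_parameter(tc, enrichment)
        except ValueError as exc:
            logger.warning("fit failed for %s/%d: %s", sequence, charge, exc)
            continue
        if not fit.converged:
            logger.warning("non-converged fit for %s/%d", sequence, charge)
            continue
        fits[key] = fit
        courses[key] = tc
        record = PeptideRateRecord(
            sequence=sequence,
            charge=charge,
            k=fit.k,
            ci_lower=fit.ci_lower,
            ci_upper=fit.ci_upper,
            pearson_r=fit.pearson_r,
            R2=fit.R2,
            RMSE=fit.RMSE,
            SD=fit.SD,
            isotope_deviation=iso_dev,
            mz=mz,
            NEH=spec.neh,
            NDP=fit.NDP,
            avg_monoisotope_abundance=tc.average_monoisotope_abundance,
            n_experiments=len(by_run),
        )
        # razor assignment: the first-listed protein owns the peptide
        records_by_protein.setdefault(proteins[0], []).append(record)

    rateconst_paths = {}
    for protein in sorted(records_by_protein):
        path = out_dir / f"{protein}.RateConst.csv"
        write_rateconst_csv(records_by_protein[protein], path)
        rateconst_paths[protein] = path

    summaries = []
    for protein in sorted(records_by_protein):
        passing = [
            rec for rec in records_by_protein[protein] if default_filter(rec)[0]
        ]
        if passing:
            summaries.append(aggregate_protein(protein, passing))
    summary_path = out_dir / "Analyzed_Proteins_and_Their_Rates.csv"
    write_protein_summary(summaries, summary_path)

    return {
        "records_by_protein": records_by_protein,
        "fits": fits,
        "courses": courses,
        "rateconst_paths": rateconst_paths,
        "summary_path": summary_path,
        "summaries": summaries,
    }


def _transfer_rt(
    key: tuple[str, int],
    by_run: dict[str, Identification],
    target_index: SpectrumIndex,
    indexes: dict[str, SpectrumIndex],
    manifest: RunManifest,
    mz: float,
    target_run: str,
) -> float | None:
    """Warp a peptide's identified rt from a source run into the target.

    The source is the run where the peptide was identified (day 0
    preferred).  Alignment uses the base-peak chromatograms of the two
    runs restricted to the peptide's elution neighborhood; if either
    window is unusable the identified rt is carried over unchanged
    (global fallback of an identity warp).
    """
    source_run = None
    for entry in manifest.runs:
        if entry.run_id in by_run and entry.run_id in indexes:
            source_run = entry.run_id
            break
    if source_run is None:
        return None
    ident = by_run[source_run]
    window = manifest.rt_window
    ref = _peptide_window_bpc(indexes[source_run], ident.rt, window, source_run)
    tgt = _peptide_window_bpc(target_index, ident.rt, window, target_run)
    if ref is None or tgt is None:
        rt_target = ident.rt
    else:
        warp = rt_alignment.cow_align(
            ref, tgt, segment_len=manifest.segment_len, slack=manifest.slack
        )
        rt_target = float(warp.inverted()(ident.rt))
    lo, hi = target_index.rt_range
    if not (lo <= rt_target <= hi):
        logger.debug("warped rt out of range for %s in %s", key, target_run)
        return None
    return rt_target


def run_refilter(
    rateconst_dir,
    criteria: FilterCriteria,
    out_path,
    pattern: str = "*.RateConst.csv",
) -> dict:
    """Re-aggregate protein rates from RateConst tables under user thresholds.

    Reads every per-protein table in ``rateconst_dir``, applies the
    criteria, Grubbs outlier removal and median aggregation, and writes
    the protein summary CSV.  Returns counts for reporting.  Inputs are
    never modified.
    """
    rateconst_dir = Path(rateconst_dir)
    paths = sorted(rateconst_dir.glob(pattern))
    if not paths:
        raise ValueError(f"no RateConst files matching {pattern} in {rateconst_dir}")
    summaries = []
    n_proteins_in = 0
    n_peptides_in = 0
    n_peptides_pass = 0
    for path in paths:
        protein = path.name[: -len(".RateConst.csv")]
        try:
            records = read_rateconst_csv(path)
        except ValueError as exc:
            logger.warning("skipping %s: %s", path, exc)
            continue
        n_proteins_in += 1
        n_peptides_in += len(records)
        passing = [rec for rec in records if custom_filter(rec, criteria)[0]]
        n_peptides_pass += len(passing)
        if passing:
            summaries.append(aggregate_protein(protein, passing))
    write_protein_summary(summaries, out_path)
    return {
        "proteins_in": n_proteins_in,
        "proteins_out": len(summaries),
        "peptides_in": n_peptides_in,
        "peptides_passing": n_peptides_pass,
        "summary_path": Path(out_path),
        "summaries": summaries,
    }
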