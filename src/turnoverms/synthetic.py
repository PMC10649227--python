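"""Synthetic heavy-water labeling data for testing and validation.

Generates peptide isotopomer time courses and full synthetic LC-MS
runs under the same forward model the fitters assume: the labeled
(newly synthesised) fraction of a protein pool grows as
f(t) = 1 - exp(-k t), the observed isotope profile is the
corresponding natural/labeled mixture, and the monoisotopic RIA
therefore decays exponentially from its natural value toward the
labeling plateau.  On top of the clean model the generator can apply
multiplicative intensity noise, an additive co-eluting contaminant on
chosen isotopomer channels, inter-run retention-time shifts and
stochastic missing identifications — the failure modes the filtering,
partial-profile and MBR machinery exist to handle.

The default configuration mirrors a murine heavy-water labeling
study design: nine labeling durations (0,1,2,3,4,5,6,14,21 days) and
4.6% body-water deuterium enrichment (a plausible steady state for
drinking water enriched to 8% after a loading bolus).

Every stochastic choice flows through one seeded numpy Generator, so a
given seed reproduces outputs exactly.
"""

from __future__ import annotations

import base64
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .isotope_model import (
    EnrichmentModel,
    PeptideSpec,
    asymptotic_ria,
    labeled_pattern,
    natural_isotope_pattern,
    ria_from_complete_profile,
)
from .kinetics import PeptideTimeCourse, TimePoint

__all__ = [
    "SimulationConfig",
    "SimulatedPeptide",
    "random_peptides",
    "simulate_timecourse",
    "simulate_runs",
    "write_mzml",
]

DEFAULT_SCHEDULE = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 14.0, 21.0)

_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SimulationConfig:
    """Knobs of the synthetic labeling experiment."""

    n_proteins: int = 3
    peptides_per_protein: int = 3
    k_bounds: tuple[float, float] = (0.005, 1.0)  # log-uniform, day^-1
    schedule: tuple[float, ...] = DEFAULT_SCHEDULE
    pW: float = 0.046
    noise_sigma: float = 0.005  # relative, on isotopomer abundances
    interference_channels: tuple[int, ...] = ()
    interference_magnitude: float = 0.0  # fraction of the base-peak abundance
    interference_fraction: float = 0.0  # fraction of peptides affected
    rt_shift_max: float = 0.0  # seconds, per labeled run
    missing_id_prob: float = 0.0
    seed: int = 0
    # spectral layout (simulate_runs only)
    run_length: float = 600.0  # seconds
    scan_interval: float = 3.0  # seconds between MS1 scans
    elution_sigma: float = 6.0  # chromatographic peak width, seconds
    base_abundance: float = 1.0e8

    def __post_init__(self) -> None:
        if 0.0 not in self.schedule:
            raise ValueError("labeling schedule must include day 0")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be nonnegative")
        self.schedule = tuple(sorted(self.schedule))

    @property
    def enrichment(self) -> EnrichmentModel:
        return EnrichmentModel(pW=self.pW)


@dataclass
class SimulatedPeptide:
    spec: PeptideSpec
    protein: str
    k: float
    rt: float  # true elution apex at day 0, seconds
    abundance: float
    interference: bool
    natural: np.ndarray = field(default_factory=lambda: np.empty(0))
    labeled: np.ndarray = field(default_factory=lambda: np.empty(0))


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    body = "".join(rng.choice(list(_RESIDUES), size=length - 1))
    return body + rng.choice(["K", "R"])


def random_peptides(
    cfg: SimulationConfig, rng: np.random.Generator
) -> list[SimulatedPeptide]:
    """Draw the peptide roster: sequences, charges, rates, elution times."""
    enr = cfg.enrichment
    peptides: list[SimulatedPeptide] = []
    n_total = cfg.n_proteins * cfg.peptides_per_protein
    n_affected = int(round(cfg.interference_fraction * n_total))
    affected = set(
        rng.choice(n_total, size=n_affected, replace=False).tolist()
    ) if n_affected else set()
    idx = 0
    for p in range(cfg.n_proteins):
        protein = f"PROT{p + 1:03d}"
        log_k = rng.uniform(np.log(cfg.k_bounds[0]), np.log(cfg.k_bounds[1]))
        k = float(np.exp(log_k))  # all peptides of a protein share its k
        for _ in range(cfg.peptides_per_protein):
            seq = _random_sequence(rng, int(rng.integers(8, 16)))
            charge = int(rng.integers(2, 4))
            spec = PeptideSpec(sequence=seq, charge=charge)
            nat = natural_isotope_pattern(spec)
            lab = labeled_pattern(nat, spec.neh, enr.excess_fraction)
            margin = 6.0 * cfg.elution_sigma + cfg.rt_shift_max
            rt = float(rng.uniform(margin, cfg.run_length - margin))
            peptides.append(
                SimulatedPeptide(
                    spec=spec,
                    protein=protein,
                    k=k,
                    rt=rt,
                    abundance=float(cfg.base_abundance * rng.uniform(0.5, 2.0)),
                    interference=idx in affected,
                    natural=nat,
                    labeled=lab,
                )
            )
            idx += 1
    return peptides


def _observed_profile(
    pep: SimulatedPeptide,
    t: float,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Raw isotopomer abundances (M0..M5) at labeling time t, with
    noise and (optionally) an additive contaminant on the configured
    channels.

    Only the six quantified channels are simulated; the mixture is
    formed between the six-peak-normalized natural and labeled
    patterns, so the noiseless complete-profile RIA is exactly linear
    in the labeled fraction f(t) = 1 - exp(-k t) and hence exactly
    exponential in time.
    """
    f = 1.0 - np.exp(-pep.k * t)
    nat6 = pep.natural[:6] / pep.natural[:6].sum()
    lab6 = pep.labeled[:6] / pep.labeled[:6].sum()
    profile = ((1.0 - f) * nat6 + f * lab6) * pep.abundance
    if cfg.noise_sigma > 0:
        profile = profile * np.maximum(
            1.0 + rng.normal(0.0, cfg.noise_sigma, size=profile.size), 0.0
        )
    if pep.interference and cfg.interference_magnitude > 0:
        # the contaminant is a different species whose abundance varies
        # from sample to sample independently of the target peptide
        bump = cfg.interference_magnitude * profile.max() * rng.uniform(0.5, 1.5)
        for ch in cfg.interference_channels:
            if ch < profile.size:
                profile[ch] += bump
    return profile


def simulate_timecourse(
    cfg: SimulationConfig,
) -> tuple[list[PeptideTimeCourse], pd.DataFrame]:
    """Per-peptide isotopomer time courses plus the ground-truth table.

    Each time course holds the raw (noisy, possibly contaminated)
    isotopomer profile and the complete-profile monoisotopic RIA at
    every scheduled time point.  The truth table records the generating
    rate, plateau RIA and interference flag per peptide.
    """
    rng = np.random.default_rng(cfg.seed)
    peptides = random_peptides(cfg, rng)
    enr = cfg.enrichment
    courses: list[PeptideTimeCourse] = []
    truth_rows = []
    for pep in peptides:
        I0_natural = ria_from_complete_profile(pep.natural)
        points = []
        for t in cfg.schedule:
            raw = _observed_profile(pep, t, cfg, rng)
            points.append(
                TimePoint(t=t, I0=ria_from_complete_profile(raw), raw=raw)
            )
        courses.append(
            PeptideTimeCourse(
                spec=pep.spec,
                points=points,
                I0_natural=I0_natural,
                average_monoisotope_abundance=pep.abundance,
            )
        )
        truth_rows.append(
            {
                "protein": pep.protein,
                "sequence": pep.spec.sequence,
                "charge": pep.spec.charge,
                "k": pep.k,
                "I0_natural": I0_natural,
                "I0_asymp": ria_from_complete_profile(pep.labeled),
                "I0_asymp_enrichment": asymptotic_ria(
                    I0_natural, enr, pep.spec.neh
                ),
                "interference": pep.interference,
                "rt": pep.rt,
                "abundance": pep.abundance,
            }
        )
    return courses, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Full synthetic runs (mzML + identification tables)


def simulate_runs(
    cfg: SimulationConfig, out_dir
) -> tuple[list[dict], pd.DataFrame]:
    """Write one centroided mzML + identification TSV per time point.

    Labeled runs carry a uniform retention-time shift (up to
    ``rt_shift_max`` seconds, drawn per run); each peptide is
    "identified" in a labeled run with probability
    1 - ``missing_id_prob`` (day 0 is always identified, anchoring the
    natural profile).  Returns the run manifest entries and the
    ground-truth table (which includes per-run shifts).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    peptides = random_peptides(cfg, rng)
    enr = cfg.enrichment
    shifts = {
        t: (0.0 if t == 0 else float(rng.uniform(-cfg.rt_shift_max, cfg.rt_shift_max)))
        for t in cfg.schedule
    }
    runs: list[dict] = []
    ident_rows_all = []
    for t in cfg.schedule:
        run_id = f"day{t:g}"
        n_scans = int(cfg.run_length / cfg.scan_interval) + 1
        scan_rts = np.arange(n_scans) * cfg.scan_interval
        profiles = []
        for pep in peptides:
            profile = _observed_profile(pep, t, cfg, rng)
            apex_rt = pep.rt + shifts[t]
            spacing = 1.003355 / pep.spec.charge
            mzs = pep.spec.mz + np.arange(profile.size) * spacing
            profiles.append((pep, profile, apex_rt, mzs))
        scans = []
        for rt in scan_rts:
            mz_list: list[float] = []
            int_list: list[float] = []
            for pep, profile, apex_rt, mzs in profiles:
                shape = np.exp(-0.5 * ((rt - apex_rt) / cfg.elution_sigma) ** 2)
                if shape < 1e-6:
                    continue
                # scale so the trapezoid area over scans equals the profile
                height = shape / (cfg.elution_sigma * np.sqrt(2.0 * np.pi))
                intensities = profile * height
                mz_list.extend(mzs)
                int_list.extend(intensities)
            order = np.argsort(mz_list) if mz_list else []
            scans.append(
                (
                    float(rt),
                    np.asarray(mz_list, dtype=float)[order],
                    np.asarray(int_list, dtype=float)[order],
                )
            )
        mzml_path = out_dir / f"{run_id}.mzML"
        write_mzml(mzml_path, run_id, scans)
        ident_rows = []
        for pep in peptides:
            if t > 0 and rng.random() < cfg.missing_id_prob:
                identified = False
            else:
                identified = True
            ident_rows_all.append(
                {
                    "run": run_id,
                    "t": t,
                    "sequence": pep.spec.sequence,
                    "charge": pep.spec.charge,
                    "identified": identified,
                    "rt_true": pep.rt + shifts[t],
                }
            )
            if identified:
                ident_rows.append(
                    {
                        "sequence": pep.spec.sequence,
                        "charge": pep.spec.charge,
                        "mz": pep.spec.mz,
                        "rt": pep.rt + shifts[t] + float(rng.normal(0.0, 1.0)),
                        "protein": pep.protein,
                        "run": run_id,
                    }
                )
        ids_path = out_dir / f"{run_id}.ids.tsv"
        pd.DataFrame(
            ident_rows,
            columns=["sequence", "charge", "mz", "rt", "protein", "run"],
        ).to_csv(ids_path, sep="\t", index=False)
        runs.append(
            {"time": t, "run_id": run_id, "mzml": str(mzml_path), "ids": str(ids_path)}
        )
    truth_rows = []
    for pep in peptides:
        I0_natural = ria_from_complete_profile(pep.natural)
        truth_rows.append(
            {
                "protein": pep.protein,
                "sequence": pep.spec.sequence,
                "charge": pep.spec.charge,
                "mz": pep.spec.mz,
                "k": pep.k,
                "I0_natural": I0_natural,
                "I0_asymp": ria_from_complete_profile(pep.labeled),
                "I0_asymp_enrichment": asymptotic_ria(
                    I0_natural, enr, pep.spec.neh
                ),
                "interference": pep.interference,
                "rt": pep.rt,
                "abundance": pep.abundance,
            }
        )
    truth = pd.DataFrame(truth_rows)
    ident_truth = pd.DataFrame(ident_rows_all)
    truth_path = out_dir / "truth.csv"
    truth.to_csv(truth_path, index=False)
    ident_truth.to_csv(out_dir / "identifications_truth.csv", index=False)
    return runs, truth


# ---------------------------------------------------------------------------
# Minimal centroided mzML writer

_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0" id="{run_id}">
  <cvList count="2">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
    <cv id="UO" fullName="Unit Ontology" URI="http://obo.cvs.sourceforge.net/obo/obo/ontology/phenotype/unit.obo"/>
  </cvList>
  <run id="{run_id}">
    <spectrumList count="{count}" defaultDataProcessingRef="dp">
"""

_MZML_SPECTRUM = """      <spectrum index="{index}" id="scan={scan}" defaultArrayLength="{length}">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
        <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
        <scanList count="1">
          <cvParam cvRef="MS" accession="MS:1000795" name="no combination" value=""/>
          <scan>
            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{rt}" unitCvRef="UO" unitAccession="UO:0000010" unitName="second"/>
          </scan>
        </scanList>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{mz_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
            <binary>{mz_b64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{int_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
            <binary>{int_b64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
"""

_MZML_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def _encode(values: np.ndarray) -> str:
    raw = struct.pack(f"<{values.size}d", *values.astype(float))
    return base64.b64encode(raw).decode("ascii")


def write_mzml(path, run_id: str, scans: list[tuple[float, np.ndarray, np.ndarray]]) -> None:
    """Write centroided MS1 scans as a minimal standalone mzML file.

    ``scans`` is a list of (rt seconds, m/z array, intensity array).
    The output carries only the elements quantification needs (ms
    level, scan start time, uncompressed 64-bit float arrays) and is
    readable by standard mzML parsers.
    """
    parts = [_MZML_HEADER.format(run_id=run_id, count=len(scans))]
    for i, (rt, mz, inten) in enumerate(scans):
        mz = np.asarray(mz, dtype=float)
        inten = np.asarray(inten, dtype=float)
        mz_b64 = _encode(mz)
        int_b64 = _encode(inten)
        parts.append(
            _MZML_SPECTRUM.format(
                index=i,
                scan=i + 1,
                length=mz.size,
                rt=f"{rt:.4f}",
                mz_len=len(mz_b64),
                mz_b64=mz_b64,
                int_len=len(int_b64),
                int_b64=int_b64,
            )
        )
    parts.append(_MZML_FOOTER)
    Path(path).write_text("".join(parts))
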