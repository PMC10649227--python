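"""Spectral quantification: XIC extraction and elution-peak integration.

Reads centroided mzML (via pyteomics) together with peptide
identifications, extracts one ion chromatogram per mass isotopomer
(M0..M5, spaced by 1.003355/charge Th) inside a ppm window, finds the
elution peak on the summed M0+M1 trace and integrates all isotopomer
traces over the same bounds — shared bounds keep the isotopomer ratios
unbiased by boundary selection.
"""

from __future__ import annotations

import base64
import struct
import zlib
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field

import numpy as np
from lxml import etree

from .rt_alignment import Chromatogram

__all__ = [
    "SpectrumIndex",
    "Identification",
    "read_mzml",
    "read_identifications_tsv",
    "extract_isotopomer_xics",
    "integrate_profile",
]

ISOTOPE_SPACING = 1.003355  # Th at charge 1 (13C - 12C)
DEFAULT_N_ISOTOPOMERS = 6
DEFAULT_PPM_TOL = 10.0
DEFAULT_RT_WINDOW = 120.0  # seconds each side of the identification
APEX_FRACTION = 0.05  # elution bounds: contiguous region above 5% of apex


@dataclass
class Identification:
    """One peptide-spectrum match (or its tabular equivalent)."""

    sequence: str
    charge: int
    mz: float
    rt: float  # seconds
    proteins: list[str] = field(default_factory=list)
    run_id: str = ""

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        if self.mz <= 0:
            raise ValueError("m/z must be positive")


class SpectrumIndex:
    """RT-ordered MS1 scans of one run, with sorted m/z arrays."""

    def __init__(self, run_id: str, scans: list[tuple[float, np.ndarray, np.ndarray]]):
        self.run_id = run_id
        scans = sorted(scans, key=lambda s: s[0])
        self.rts = np.array([s[0] for s in scans], dtype=float)
        self.mz_arrays = [np.asarray(s[1], dtype=float) for s in scans]
        self.intensity_arrays = [np.asarray(s[2], dtype=float) for s in scans]

    def __len__(self) -> int:
        return self.rts.size

    @property
    def rt_range(self) -> tuple[float, float]:
        if self.rts.size == 0:
            return (0.0, 0.0)
        return float(self.rts[0]), float(self.rts[-1])

    def scan_slice(self, rt_lo: float, rt_hi: float) -> range:
        return range(
            bisect_left(self.rts, rt_lo), bisect_right(self.rts, rt_hi)
        )


# mzML CV accessions used by the reader
_ACC_MS_LEVEL = "MS:1000511"
_ACC_PROFILE = "MS:1000128"
_ACC_SCAN_START = "MS:1000016"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_NOCOMP = "MS:1000576"


def _decode_binary_array(bda) -> tuple[str | None, np.ndarray]:
    """Decode one <binaryDataArray>: returns (array kind, values)."""
    kind = None
    dtype = "d"
    compressed = False
    payload = ""
    for child in bda.iter():
        tag = etree.QName(child).localname
        if tag == "cvParam":
            acc = child.get("accession")
            if acc == _ACC_MZ_ARRAY:
                kind = "mz"
            elif acc == _ACC_INT_ARRAY:
                kind = "intensity"
            elif acc == _ACC_F32:
                dtype = "f"
            elif acc == _ACC_ZLIB:
                compressed = True
        elif tag == "binary":
            payload = child.text or ""
    raw = base64.b64decode(payload)
    if compressed:
        raw = zlib.decompress(raw)
    width = 8 if dtype == "d" else 4
    n = len(raw) // width
    return kind, np.asarray(struct.unpack(f"<{n}{dtype}", raw), dtype=float)


def read_mzml(path, run_id: str | None = None) -> SpectrumIndex:
    """Index the MS1 scans of a centroided mzML file.

    A minimal standalone mzML reader covering centroided spectra with
    64-/32-bit float arrays, zlib-compressed or plain.  Profile-mode
    spectra are rejected: peak picking belongs upstream.
    """
    scans = []
    for _, elem in etree.iterparse(str(path), tag="{*}spectrum"):
        ms_level = None
        rt = None
        arrays: dict[str, np.ndarray] = {}
        for child in elem.iter():
            tag = etree.QName(child).localname
            if tag == "cvParam":
                acc = child.get("accession")
                if acc == _ACC_MS_LEVEL:
                    ms_level = int(child.get("value"))
                elif acc == _ACC_PROFILE:
                    raise ValueError(
                        f"{path}: profile-mode spectra are not supported; "
                        "centroid the data first"
                    )
                elif acc == _ACC_SCAN_START:
                    rt = float(child.get("value"))
                    if child.get("unitName", "").startswith("minute"):
                        rt *= 60.0
            elif tag == "binaryDataArray":
                kind, values = _decode_binary_array(child)
                if kind:
                    arrays[kind] = values
        if ms_level == 1 and rt is not None and "mz" in arrays:
            scans.append((rt, arrays["mz"], arrays.get("intensity", np.zeros(0))))
        elem.clear(keep_tail=True)
    if run_id is None:
        run_id = str(path)
    return SpectrumIndex(run_id, scans)


def read_identifications_tsv(path, run_id: str | None = None) -> list[Identification]:
    """Read the documented TSV identification format.

    Tab-separated with header: sequence, charge, mz, rt, protein, run.
    ``protein`` may hold several accessions separated by ';'.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    required = {"sequence", "charge", "mz", "rt", "protein"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing identification columns: {missing}")
    idents = []
    for _, row in df.iterrows():
        idents.append(
            Identification(
                sequence=str(row["sequence"]),
                charge=int(row["charge"]),
                mz=float(row["mz"]),
                rt=float(row["rt"]),
                proteins=str(row["protein"]).split(";"),
                run_id=run_id or str(row.get("run", "")),
            )
        )
    return idents


def extract_isotopomer_xics(
    index: SpectrumIndex,
    ident: Identification,
    n_isotopomers: int = DEFAULT_N_ISOTOPOMERS,
    ppm_tol: float = DEFAULT_PPM_TOL,
    rt_window: float = DEFAULT_RT_WINDOW,
    rt_center: float | None = None,
) -> list[Chromatogram]:
    """Extracted ion chromatograms for M0..M(n-1) of one peptide.

    Isotopomer i is extracted at mz + i*1.003355/charge within
    ``ppm_tol``; intensities of all matching centroids in a scan are
    summed.  ``rt_center`` overrides the identification's rt (used for
    MBR-transferred windows).  Returns empty chromatogram stubs when no
    scan falls inside the window.
    """
    if ppm_tol <= 0:
        raise ValueError("ppm tolerance must be positive")
    if n_isotopomers < 1:
        raise ValueError("need at least one isotopomer")
    center = ident.rt if rt_center is None else rt_center
    scan_idx = list(index.scan_slice(center - rt_window, center + rt_window))
    targets = ident.mz + np.arange(n_isotopomers) * ISOTOPE_SPACING / ident.charge
    if not scan_idx:
        return []
    rts = index.rts[scan_idx]
    traces = np.zeros((n_isotopomers, len(scan_idx)))
    for col, s in enumerate(scan_idx):
        mz_arr = index.mz_arrays[s]
        int_arr = index.intensity_arrays[s]
        for row, mz_t in enumerate(targets):
            tol = mz_t * ppm_tol * 1e-6
            lo = np.searchsorted(mz_arr, mz_t - tol, side="left")
            hi = np.searchsorted(mz_arr, mz_t + tol, side="right")
            if hi > lo:
                traces[row, col] = int_arr[lo:hi].sum()
    if rts.size < 2:
        return []
    return [
        Chromatogram(rt=rts, intensity=traces[i], run_id=index.run_id)
        for i in range(n_isotopomers)
    ]


def _smooth3(x: np.ndarray) -> np.ndarray:
    if x.size < 3:
        return x.copy()
    out = np.convolve(x, np.ones(3) / 3.0, mode="same")
    out[0], out[-1] = x[0], x[-1]
    return out


def integrate_profile(
    xics: list[Chromatogram],
) -> tuple[np.ndarray, float] | None:
    """Integrate isotopomer XICs over shared elution bounds.

    The elution window is found on the 3-point-smoothed M0+M1 summed
    trace: the apex scan plus the contiguous region above 5% of the
    apex.  Every isotopomer is trapezoid-integrated over those same
    bounds.  Returns (raw abundances A0..A(n-1), mean M0 intensity over
    the window), or ``None`` when nothing was detected.
    """
    if not xics or xics[0].intensity.sum() <= 0:
        return None
    anchor = xics[0].intensity.copy()
    if len(xics) > 1:
        anchor = anchor + xics[1].intensity
    smoothed = _smooth3(anchor)
    apex = int(np.argmax(smoothed))
    if smoothed[apex] <= 0:
        return None
    threshold = APEX_FRACTION * smoothed[apex]
    lo = apex
    while lo > 0 and smoothed[lo - 1] >= threshold:
        lo -= 1
    hi = apex
    while hi < smoothed.size - 1 and smoothed[hi + 1] >= threshold:
        hi += 1
    if hi == lo:
        hi = min(hi + 1, smoothed.size - 1)
        lo = max(lo - 1, 0)
    rt = xics[0].rt[lo : hi + 1]
    areas = np.array(
        [np.trapezoid(x.intensity[lo : hi + 1], rt) for x in xics]
    )
    avg_m0 = float(xics[0].intensity[lo : hi + 1].mean())
    if areas[0] <= 0:
        return None
    return areas, avg_m0
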