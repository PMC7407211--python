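"""Compound identification from all-ion-fragmentation runs.

Identity is established by three criteria: (1) a peak on the MS1 extracted
chromatogram of the analyte ion (±5 ppm), (2) a co-eluting peak on the
fragment-level (AIF) chromatogram of at least one class-diagnostic
fragment, and (3) a retention-time match against a reference standard
(or, where no standard exists, a class-internal RT prediction). The same
machinery drives untargeted screening: candidate bile-acid conjugates and
lysophospholipids are enumerated from composition space and each MS1 hit
is scored by the fraction of expected diagnostic fragments that co-elute.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chemmass import (
    Adduct,
    DiagnosticFragment,
    Formula,
    LPL_CLASS_INFO,
    acyl_formula,
    fragment_registry,
    ion_mz,
    lpl_formula,
    monoisotopic_mass,
    parse_formula,
)
from .peakcraft import Peak, XIC, coelute, detect_peaks, extract_xic
from .spectra_io import CompoundEntry, Run

__all__ = [
    "Annotation",
    "CandidateHit",
    "SnAssignment",
    "confirm_identity",
    "screen_bile_acids",
    "screen_lpl",
    "assign_sn_isomers",
    "predict_rt",
    "fragments_for_tags",
    "bile_acid_candidate_space",
]

DEFAULT_PPM = 5.0
DEFAULT_RT_TOL = 0.1  # minutes
RT_PREDICTION_TOL = 0.3  # minutes, tolerance attached to predicted RTs

#: class tags that define no diagnostic fragments (unconjugated bile acids
#: fragment poorly in negative mode; identity rests on mass + RT)
_FRAGMENTLESS_TAGS = {"bile-acid"}


def fragments_for_tags(class_tag: str) -> list[DiagnosticFragment]:
    """Diagnostic fragments for a (possibly ``+``-combined) class tag."""
    frags: list[DiagnosticFragment] = []
    for tag in class_tag.split("+"):
        if tag in _FRAGMENTLESS_TAGS:
            continue
        frags.extend(fragment_registry(tag))
    return frags


def observable_fragment_mzs(
    frags: list[DiagnosticFragment], precursor_mz: float
) -> list[tuple[str, float]]:
    """(name, m/z) for each fragment channel that can be extracted: anion
    fragments at their own m/z, neutral losses at precursor - loss."""
    out = []
    for f in frags:
        if f.ion_composition is not None:
            out.append((f.name, f.mz))
        else:
            out.append((f.name, precursor_mz - monoisotopic_mass(f.neutral_loss)))
    return out


@dataclass
class Annotation:
    """Three-criteria identification result for one library compound."""

    compound: CompoundEntry
    ms1_peak: Peak | None
    criterion_ms1: bool
    criterion_ms2_fragment: bool
    matched_fragments: list[str] = field(default_factory=list)
    criterion_rt: bool = False
    confirmed: bool = False
    isomer_label: str | None = None
    estimated_concentration: float | None = None


@dataclass
class CandidateHit:
    """One untargeted-screen hit: an MS1 peak matching a candidate mass,
    scored by co-eluting diagnostic fragments."""

    query_mz: float
    class_hypothesis: str
    apex_rt: float
    matched_fragments: list[str]
    score: float
    mass_only: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must be in [0, 1]")


def _best_peak(peaks: list[Peak], expected_rt: float | None) -> Peak | None:
    if not peaks:
        return None
    if expected_rt is None:
        return max(peaks, key=lambda p: p.height)
    return min(peaks, key=lambda p: abs(p.apex_rt - expected_rt))


def confirm_identity(
    run: Run,
    compound: CompoundEntry,
    rt_tol: float = DEFAULT_RT_TOL,
    ppm: float = DEFAULT_PPM,
    min_snr: float = 3.0,
) -> Annotation:
    """Apply the three identification criteria to one library compound.

    For classes that define no diagnostic fragments the fragment criterion
    is vacuously satisfied (there is nothing to look for); identification
    then rests on accurate mass and retention time alone.
    """
    precursor = ion_mz(compound.neutral_formula, compound.adduct)
    xic1 = extract_xic(run, precursor.mz, ppm, ms_level=1)
    ms1_peaks = detect_peaks(xic1, min_snr=min_snr)
    peak = _best_peak(ms1_peaks, compound.expected_rt)
    criterion_ms1 = peak is not None

    frags = fragments_for_tags(compound.class_tag)
    matched: list[str] = []
    if not frags:
        criterion_ms2 = True  # vacuous: class defines no fragments
    elif peak is None:
        criterion_ms2 = False
    else:
        for name, fmz in observable_fragment_mzs(frags, precursor.mz):
            fxic = extract_xic(run, fmz, ppm, ms_level=2)
            for fpeak in detect_peaks(fxic, min_snr=min_snr):
                if coelute(peak, fpeak, rt_tol):
                    matched.append(name)
                    break
        criterion_ms2 = bool(matched)

    criterion_rt = (
        peak is not None
        and compound.expected_rt is not None
        and abs(peak.apex_rt - compound.expected_rt) <= rt_tol
    )
    confirmed = (
        criterion_ms1
        and criterion_ms2
        and (criterion_rt or compound.rt_source == "predicted")
    )
    return Annotation(
        compound=compound,
        ms1_peak=peak,
        criterion_ms1=criterion_ms1,
        criterion_ms2_fragment=criterion_ms2,
        matched_fragments=matched,
        criterion_rt=criterion_rt,
        confirmed=confirmed,
    )


# --------------------------------------------------------------------------
# Untargeted screens
# --------------------------------------------------------------------------

#: composition deltas added to a bile-acid core by each conjugation
_CONJUGATIONS: dict[str, Formula] = {
    "glycine": parse_formula("C2H3NO"),
    "taurine": parse_formula("C2H5NO2S"),
    "sulfate": parse_formula("O3S"),
    "glucuronide": parse_formula("C6H8O6"),
}
_CONJ_TAG = {
    "glycine": "glycine-conjugate",
    "taurine": "taurine-conjugate",
    "sulfate": "sulfate",
    "glucuronide": "glucuronide",
}
#: C24 cholanoic acid cores with 1-3 hydroxyls
_BA_CORES = {
    "BA(1OH)": parse_formula("C24H40O3"),
    "BA(2OH)": parse_formula("C24H40O4"),
    "BA(3OH)": parse_formula("C24H40O5"),
}


def bile_acid_candidate_space() -> list[tuple[str, Formula, str]]:
    """(hypothesis label, neutral formula, class tag) for all cores x
    conjugation sets of size 0-2 (unordered, no repeats)."""
    conj_names = list(_CONJUGATIONS)
    combos: list[tuple[str, ...]] = [()]
    combos += [(c,) for c in conj_names]
    combos += [
        (a, b)
        for i, a in enumerate(conj_names)
        for b in conj_names[i + 1 :]
    ]
    space = []
    for core_name, core in _BA_CORES.items():
        for combo in combos:
            formula = core
            for c in combo:
                formula = formula + _CONJUGATIONS[c]
            label = core_name + "".join(f"+{c}" for c in combo)
            tag = "+".join(_CONJ_TAG[c] for c in combo) if combo else "bile-acid"
            space.append((label, formula, tag))
    return space


def _screen_candidates(
    run: Run,
    candidates: list[tuple[str, Formula, str, str]],
    ppm: float,
    rt_tol: float,
    min_snr: float,
    require_fragment: bool,
) -> list[CandidateHit]:
    lo, hi = run.metadata.get("ms1_range", (370.0, 700.0))
    hits: list[CandidateHit] = []
    frag_xic_cache: dict[float, list[Peak]] = {}

    def frag_peaks(fmz: float) -> list[Peak]:
        key = round(fmz, 5)
        if key not in frag_xic_cache:
            frag_xic_cache[key] = detect_peaks(
                extract_xic(run, fmz, ppm, ms_level=2), min_snr=min_snr
            )
        return frag_xic_cache[key]

    for label, formula, tag, adduct in candidates:
        mz = ion_mz(formula, adduct).mz
        if not lo <= mz <= hi:
            continue
        peaks = detect_peaks(extract_xic(run, mz, ppm, ms_level=1), min_snr=min_snr)
        if not peaks:
            continue
        frags = fragments_for_tags(tag)
        channels = observable_fragment_mzs(frags, mz)
        for peak in peaks:
            matched = []
            for name, fmz in channels:
                if any(coelute(peak, fp, rt_tol) for fp in frag_peaks(fmz)):
                    matched.append(name)
            score = len(matched) / len(channels) if channels else 0.0
            mass_only = not matched
            if require_fragment and channels and not matched:
                continue
            hits.append(
                CandidateHit(
                    query_mz=mz,
                    class_hypothesis=label,
                    apex_rt=peak.apex_rt,
                    matched_fragments=matched,
                    score=score,
                    mass_only=mass_only,
                )
            )
    return hits


def screen_bile_acids(
    run: Run,
    candidate_space: list[tuple[str, Formula, str]] | None = None,
    ppm: float = DEFAULT_PPM,
    rt_tol: float = DEFAULT_RT_TOL,
    min_snr: float = 3.0,
) -> list[CandidateHit]:
    """Screen a run against the bile-acid conjugate candidate space.

    Every MS1 peak matching a candidate [M-H]- mass becomes a hit;
    conjugated candidates are scored by which conjugate fragments co-elute
    and unconjugated candidates are reported as mass-only with score 0.
    """
    space = candidate_space if candidate_space is not None else bile_acid_candidate_space()
    if not space:
        raise ValueError("empty candidate space")
    candidates = [
        (label, formula, tag, Adduct.DEPROTONATED) for label, formula, tag in space
    ]
    return _screen_candidates(run, candidates, ppm, rt_tol, min_snr, require_fragment=False)


def screen_lpl(
    run: Run,
    acyl_space: list[tuple[int, int]] | None = None,
    classes: tuple[str, ...] = ("LPC", "O-LPC", "LPE", "LPI", "LPS", "LPG"),
    ppm: float = DEFAULT_PPM,
    rt_tol: float = DEFAULT_RT_TOL,
    min_snr: float = 3.0,
) -> list[CandidateHit]:
    """Screen a run for lysophospholipids across chain space.

    A hit requires an MS1 peak plus a co-eluting acyl carboxylate and/or
    head-group fragment; MS1-only matches are reported as mass-only. The
    class is fixed by the head group and its adduct rule (choline classes
    are detected as acetate adducts, the rest deprotonated), the acyl
    chain by the carboxylate fragment.
    """
    if acyl_space is None:
        acyl_space = [(c, d) for c in range(12, 23) for d in range(0, 7)]
    candidates = []
    for cls in classes:
        head_tag, adduct = LPL_CLASS_INFO[cls]
        for carbons, db in acyl_space:
            tag = head_tag if cls == "O-LPC" else f"{head_tag}+fatty-acyl({carbons}:{db})"
            candidates.append(
                (f"{cls}({carbons}:{db})", lpl_formula(cls, carbons, db), tag, adduct)
            )
    hits = _screen_candidates(
        run, candidates, ppm, rt_tol, min_snr, require_fragment=False
    )
    return hits


# --------------------------------------------------------------------------
# sn-positional isomers
# --------------------------------------------------------------------------


@dataclass
class SnAssignment:
    """Labels aligned with the input peak order; ``consistent`` records
    whether the minor peak of a pair eluted first, as expected for 2-acyl
    (sn-2) isomers on this separation."""

    labels: list[str | None]
    consistent: bool | None = None


def assign_sn_isomers(
    peaks: list[Peak],
    rt_offset_range: tuple[float, float] = (0.15, 0.5),
    ratio_max: float = 0.35,
    sn2_first: bool = True,
) -> SnAssignment:
    """Label the sn-1/sn-2 positional isomer pair of one lysophospholipid.

    With exactly two peaks whose apex offset falls in ``rt_offset_range``
    and whose minor/major area ratio is at most ``ratio_max``, the earlier
    peak is labelled sn2 and the later sn1 (``sn2_first=False`` swaps the
    convention). Any other configuration labels only the dominant peak as
    sn1. The consistency flag reports whether the minor peak eluted first.
    """
    if not peaks:
        raise ValueError("no peaks to label")
    order = sorted(range(len(peaks)), key=lambda i: peaks[i].apex_rt)
    labels: list[str | None] = [None] * len(peaks)
    if len(peaks) == 2:
        first, second = order
        offset = peaks[second].apex_rt - peaks[first].apex_rt
        areas = [peaks[i].area for i in (first, second)]
        minor_first = areas[0] < areas[1]
        ratio = min(areas) / max(areas) if max(areas) > 0 else 1.0
        if rt_offset_range[0] <= offset <= rt_offset_range[1] and ratio <= ratio_max:
            if sn2_first:
                labels[first], labels[second] = "sn2", "sn1"
            else:
                labels[first], labels[second] = "sn1", "sn2"
            return SnAssignment(labels=labels, consistent=minor_first)
        dominant = max(range(len(peaks)), key=lambda i: peaks[i].area)
        labels[dominant] = "sn1"
        return SnAssignment(labels=labels, consistent=minor_first)
    dominant = max(range(len(peaks)), key=lambda i: peaks[i].area)
    labels[dominant] = "sn1"
    return SnAssignment(labels=labels, consistent=None)


def predict_rt(
    class_tag: str,
    carbons: int,
    double_bonds: int,
    anchors: list[tuple[int, int, float]],
) -> float:
    """Predict a retention time from class anchors.

    Fits rt = a + b*carbons + c*double_bonds by least squares over the
    anchors of one LPL class (equivalent-carbon-number behaviour on a
    reversed-phase gradient: longer chains retained more, double bonds
    less). Predictions carry a ±``RT_PREDICTION_TOL`` tolerance.
    """
    if len(anchors) < 3:
        raise ValueError("need at least 3 anchors for RT prediction")
    A = np.array([[1.0, c, d] for c, d, _ in anchors])
    y = np.array([rt for _, _, rt in anchors])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(coef @ [1.0, carbons, double_bonds])
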