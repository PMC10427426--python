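"""Seeded synthetic-data generators for every pipeline input.

Each generator is a pure function of (config, seed) and returns both
the inputs the pipeline consumes and the ground truth needed to verify
every planted quantity, so all stages are testable fully offline:

* ``gen_ihc_cohort`` — two-group cohorts of brightfield IHC slides
  rendered by forward Beer-Lambert stain mixing, with planted per-patch
  tissue-class composition differences between responders and
  non-responders (the non-responder excess sits on a stroma-like
  low-DAB class);
* ``gen_paired_variants`` — paired baseline/resistance variant tables
  with planted coverage-regime rescue cases, acquired alterations,
  germline contaminants and copy-number segment constructions;
* ``gen_trial_outcomes`` — per-cohort Bernoulli confirmed-response
  records;
* ``gen_cell_maps`` — paired multiplex-IF cell maps as marked spatial
  Poisson processes with a planted on-treatment density ratio on
  CK+/PD-L1+ tumor cells.

A master seed spawns independent per-artifact substreams, so
regenerating one artifact never shifts another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .her2_spatial import PATCH_SIZE, SlideImage
from .nuclei_morphometrics import DEFAULT_BASIS, StainBasis
from .paired_genomics import CnaSegment, PileupCount, VariantCall, rescue_threshold

__all__ = [
    "IhcClassSpec",
    "SyntheticCohortConfig",
    "SlideTruth",
    "IhcCohort",
    "PairedVariantCohort",
    "RescueCase",
    "gen_ihc_cohort",
    "gen_paired_variants",
    "gen_trial_outcomes",
    "gen_cell_maps",
    "DEFAULT_IHC_CLASSES",
]


@dataclass(frozen=True)
class IhcClassSpec:
    """One planted tissue class: its DAB optical-density level (HER2
    staining intensity), expected nuclei count per 64 px patch, and
    nucleus radius (um)."""

    dab_od: float
    nuclei_per_patch: float
    nucleus_radius_um: float = 1.7


#: Eight planted classes on a DAB-intensity x cell-density x
#: nucleus-size grid, so each class is a well-separated mode in
#: appearance space.  Class 0 is the stroma-like class: essentially
#: unstained with sparse-to-moderate small nuclei.
DEFAULT_IHC_CLASSES = (
    IhcClassSpec(0.06, 6.0, 1.5),   # stroma-like low-DAB
    IhcClassSpec(0.06, 22.0, 2.6),
    IhcClassSpec(0.45, 6.0, 2.6),
    IhcClassSpec(0.45, 22.0, 1.5),
    IhcClassSpec(1.00, 6.0, 1.5),
    IhcClassSpec(1.00, 22.0, 2.6),
    IhcClassSpec(1.60, 6.0, 2.6),
    IhcClassSpec(1.60, 22.0, 1.5),
)


@dataclass
class SyntheticCohortConfig:
    """Study conditions for all generators.

    Image parameters default to 512 px slides at 0.325 um/px with 12
    slides per response group and eight planted classes; the
    non-responder group carries a +0.15 excess of the stroma-like
    class.  Variant parameters default to 11 baseline/resistance pairs
    with coverage regimes below 100x, 100-499x and 500x and above.
    """

    # --- IHC cohort ---
    n_slides_per_group: int = 12
    image_size: int = 512
    microns_per_pixel: float = 0.325
    classes: Sequence[IhcClassSpec] = DEFAULT_IHC_CLASSES
    stroma_class: int = 0
    effect_size: float = 0.15  # excess stroma proportion in non-responders
    dirichlet_concentration: float = 60.0
    tissue_radius_frac: float = 0.45
    hematoxylin_wash_od: float = 0.06
    nucleus_od: float = 0.90
    noise_sd: float = 2.0  # additive, transmitted-intensity counts
    background_intensity: float = 245.0
    stain_basis: StainBasis = DEFAULT_BASIS
    # --- paired variants ---
    n_patients: int = 11
    n_shared_mutations: int = 4
    coverage_regimes: tuple[int, ...] = (60, 250, 800)
    acquired_mutation_genes: tuple[str, ...] = ("SLX4", "NFKBIA")
    acquired_cna_gene: str = "CDKN2A"
    decoy_cna_gene: str = "RB1"
    germline_rate: float = 0.1
    n_unmatched_normal: int = 3
    # --- trial outcomes ---
    cohort_sizes: tuple[int, ...] = (68, 72, 37)
    response_probs: tuple[float, ...] = (0.706, 0.375, 0.297)
    # --- cell maps ---
    n_pairs: int = 18
    map_width_um: float = 1400.0
    map_height_um: float = 1500.0
    ck_per_mm2: float = 400.0
    pdl1_pos_fraction: float = 0.25
    cd3_per_mm2: float = 150.0
    cd68_per_mm2: float = 80.0
    on_treatment_ratio: float = 1.0  # CK+/PD-L1+ density ratio on treatment
    patient_lognorm_sd: float = 0.3

    def __post_init__(self) -> None:
        if not (0.0 <= self.effect_size <= 1.0):
            raise ValueError("effect_size must lie in [0,1]")
        if any(not (0.0 <= p <= 1.0) for p in self.response_probs):
            raise ValueError("response probabilities must lie in [0,1]")
        if len(self.cohort_sizes) != len(self.response_probs):
            raise ValueError("cohort_sizes and response_probs must align")


def _spawn(seed: int, label: str) -> np.random.Generator:
    """Independent substream for one artifact family."""
    # stable small integer per label keeps substreams decoupled
    tag = sum(ord(ch) * (i + 1) for i, ch in enumerate(label)) % (2**16)
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(tag,)))


# ---------------------------------------------------------------------------
# IHC cohort


@dataclass
class SlideTruth:
    """Ground truth for one synthetic slide."""

    slide_id: str
    patch_class: np.ndarray  # grid of per-patch class indices, -1 = background
    tissue_cells: np.ndarray  # boolean grid, True where tissue was rendered
    nuclei: list[tuple[float, float, float]]  # (row, col, radius) full-res px
    response: bool

    def class_of_patch(self, origin: tuple[int, int]) -> int:
        return int(self.patch_class[origin[0] // PATCH_SIZE, origin[1] // PATCH_SIZE])


@dataclass
class IhcCohort:
    slides: list[SlideImage]
    truths: dict[str, SlideTruth]
    response: dict[str, bool]
    config: SyntheticCohortConfig


def _group_mixture(config: SyntheticCohortConfig, responder: bool) -> np.ndarray:
    k = len(config.classes)
    mix = np.full(k, 1.0 / k)
    if not responder and k > 1:
        mix[config.stroma_class] += config.effect_size
        others = [i for i in range(k) if i != config.stroma_class]
        mix[others] = (1.0 - mix[config.stroma_class]) / len(others)
    return mix


def _render_slide(
    config: SyntheticCohortConfig,
    rng: np.random.Generator,
    slide_id: str,
    responder: bool,
) -> tuple[SlideImage, SlideTruth]:
    s = config.image_size
    g = s // PATCH_SIZE
    k = len(config.classes)

    # tissue footprint: one jittered disc, annotated as the slide's ROI
    # (standing in for the pathologist's region annotation).  A grid
    # cell is rendered as tissue when >= 30% of its pixels fall inside
    # the disc, so every patch at least half inside the ROI is fully
    # rendered and no blank background tile can enter the analysis.
    jitter = rng.uniform(-0.05, 0.05, size=2) * s
    cy, cx = s / 2 + jitter
    radius = config.tissue_radius_frac * s
    yy_full, xx_full = np.mgrid[0:s, 0:s]
    disc = (yy_full - cy) ** 2 + (xx_full - cx) ** 2 <= radius**2
    overlap = disc.reshape(g, PATCH_SIZE, g, PATCH_SIZE).mean(axis=(1, 3))
    tissue = overlap >= 0.3
    theta = np.linspace(0.0, 2.0 * math.pi, 64, endpoint=False)
    roi_ring = [(cx + radius * math.cos(t), cy + radius * math.sin(t)) for t in theta]

    mix = rng.dirichlet(config.dirichlet_concentration * _group_mixture(config, responder))
    patch_class = np.full((g, g), -1, dtype=int)
    n_tissue = int(tissue.sum())
    patch_class[tissue] = rng.choice(k, size=n_tissue, p=mix)

    c_h = np.zeros((s, s))
    c_d = np.zeros((s, s))
    nuclei: list[tuple[float, float, float]] = []
    yy, xx = np.mgrid[0:PATCH_SIZE, 0:PATCH_SIZE]
    for gi in range(g):
        for gj in range(g):
            cls = patch_class[gi, gj]
            if cls < 0:
                continue
            spec = config.classes[cls]
            nuc_r_px = spec.nucleus_radius_um / config.microns_per_pixel
            r0, c0 = gi * PATCH_SIZE, gj * PATCH_SIZE
            block_d = np.full((PATCH_SIZE, PATCH_SIZE), spec.dab_od)
            block_d *= 1.0 + 0.08 * rng.standard_normal((PATCH_SIZE, PATCH_SIZE))
            c_d[r0 : r0 + PATCH_SIZE, c0 : c0 + PATCH_SIZE] = np.clip(block_d, 0.0, None)
            block_h = np.full((PATCH_SIZE, PATCH_SIZE), config.hematoxylin_wash_od)
            # under-dispersed counts (hard-core repulsion between nuclei
            # makes real per-patch counts narrower than Poisson)
            n_nuc = max(0, int(round(rng.normal(spec.nuclei_per_patch,
                                                0.2 * spec.nuclei_per_patch))))
            margin = math.ceil(nuc_r_px) + 1
            for _ in range(n_nuc):
                py = rng.uniform(margin, PATCH_SIZE - margin)
                px = rng.uniform(margin, PATCH_SIZE - margin)
                rad = float(np.clip(rng.normal(nuc_r_px, 0.10 * nuc_r_px), 0.6 * nuc_r_px, 1.5 * nuc_r_px))
                disc = (yy - py) ** 2 + (xx - px) ** 2 <= rad**2
                block_h[disc] += config.nucleus_od
                nuclei.append((r0 + py, c0 + px, rad))
            c_h[r0 : r0 + PATCH_SIZE, c0 : c0 + PATCH_SIZE] = block_h

    basis = config.stain_basis.matrix()  # 3 x 2, unit columns
    od = c_h[..., None] * basis[:, 0] + c_d[..., None] * basis[:, 1]
    transmitted = config.background_intensity * np.power(10.0, -od)
    transmitted += config.noise_sd * rng.standard_normal(transmitted.shape)
    pixels = np.clip(transmitted, 0, 255).astype(np.uint8)

    slide = SlideImage(
        pixels=pixels, microns_per_pixel=config.microns_per_pixel, slide_id=slide_id,
        rois=[roi_ring],
    )
    truth = SlideTruth(
        slide_id=slide_id, patch_class=patch_class, tissue_cells=tissue,
        nuclei=nuclei, response=responder,
    )
    return slide, truth


def gen_ihc_cohort(
    config: Optional[SyntheticCohortConfig] = None, seed: int = 0
) -> IhcCohort:
    """Two-group IHC slide cohort with per-patch class ground truth."""
    config = config or SyntheticCohortConfig()
    rng = _spawn(seed, "ihc")
    slides: list[SlideImage] = []
    truths: dict[str, SlideTruth] = {}
    response: dict[str, bool] = {}
    for group, responder in (("R", True), ("NR", False)):
        for i in range(config.n_slides_per_group):
            sid = f"{group}{i:02d}"
            slide, truth = _render_slide(config, rng, sid, responder)
            slides.append(slide)
            truths[sid] = truth
            response[sid] = responder
    return IhcCohort(slides=slides, truths=truths, response=response, config=config)


# ---------------------------------------------------------------------------
# Paired variants


@dataclass(frozen=True)
class RescueCase:
    """A planted mutation eligible for rescue in the paired sample."""

    patient: str
    key: tuple[str, int, str, str]
    coverage: int
    alt_reads: int
    rescuable: bool
    target_timepoint: str  # the timepoint the call should be rescued into


@dataclass
class PairedVariantCohort:
    patients: list[str]
    calls: dict[tuple[str, str], list[VariantCall]]  # (patient, timepoint) -> calls
    pileups: dict[tuple[str, str], list[PileupCount]]  # pileup IN that sample
    segments: list[CnaSegment]
    has_matched_normal: dict[str, bool]
    rescue_cases: list[RescueCase]
    acquired_genes: list[str]  # planted true acquired genes
    decoy_genes: list[str]  # planted near-miss genes (must NOT be called)
    germline_keys: dict[str, set]


_BASES = ("A", "C", "G", "T")

#: The deterministic coverage x alt-read grid of planted rescue cases.
RESCUE_GRID = tuple((cov, alt) for cov in (99, 100, 499, 500, 501) for alt in (1, 2, 3))


def _random_variant(rng: np.random.Generator, chrom: str, pos: int) -> tuple[str, str]:
    ref = _BASES[rng.integers(4)]
    alt = _BASES[(rng.integers(1, 4) + _BASES.index(ref)) % 4]
    return ref, alt


def gen_paired_variants(
    config: Optional[SyntheticCohortConfig] = None, seed: int = 0
) -> PairedVariantCohort:
    """Paired baseline/resistance variant cohort with planted events.

    Plants (a) shared clonal mutations visible at both timepoints with
    coverage drawn from the three regimes; (b) the deterministic
    coverage x alt-read rescue grid as baseline-only calls with a
    resistance pileup; (c) acquired mutations in at least two
    resistance samples for the truth genes, plus a copy-number-only
    acquired gene in three samples and a two-sample decoy that must
    stay below the CNA-only threshold; (d) germline contaminants; and
    (e) the copy-number segment constructions exercising the focality
    and second-run substitution rules.
    """
    config = config or SyntheticCohortConfig()
    rng = _spawn(seed, "variants")
    patients = [f"P{i:02d}" for i in range(config.n_patients)]
    calls: dict[tuple[str, str], list[VariantCall]] = {
        (p, tp): [] for p in patients for tp in ("baseline", "resistance")
    }
    pileups: dict[tuple[str, str], list[PileupCount]] = {
        (p, tp): [] for p in patients for tp in ("baseline", "resistance")
    }
    segments: list[CnaSegment] = []
    germline_keys: dict[str, set] = {p: set() for p in patients}
    rescue_cases: list[RescueCase] = []

    reserved = set(config.acquired_mutation_genes) | {
        config.acquired_cna_gene, config.decoy_cna_gene,
    }
    shared_pool = [g for g in (
        "TP53", "PIK3CA", "PTEN", "ERBB2", "GATA3", "MAP3K1", "CDH1", "ESR1", "AKT1",
    ) if g not in reserved]

    pos_counter = 1_000_000

    def next_pos() -> int:
        nonlocal pos_counter
        pos_counter += 1_000
        return pos_counter

    def add_pair_presence(
        patient: str, gene: str, chrom: str, vaf: float,
        baseline_called: bool, resistance_called: bool,
        res_pileup: Optional[tuple[int, int]] = None,
        base_pileup: Optional[tuple[int, int]] = None,
        germline: bool = False,
    ) -> tuple[str, int, str, str]:
        pos = next_pos()
        ref, alt = _random_variant(rng, chrom, pos)
        key = (chrom, pos, ref, alt)
        for tp, called in (("baseline", baseline_called), ("resistance", resistance_called)):
            if called:
                depth = int(rng.choice(config.coverage_regimes))
                alt_reads = max(1, int(round(vaf * depth)))
                calls[(patient, tp)].append(
                    VariantCall(
                        sample_id=f"{patient}-{'T1' if tp == 'baseline' else 'T2'}",
                        timepoint=tp, chrom=chrom, pos=pos, ref=ref, alt=alt,
                        vaf=min(alt_reads / depth, 1.0), depth=depth,
                        alt_reads=alt_reads, germline_flag=germline, gene=gene,
                        consequence="missense",
                    )
                )
        # pileup rows in the OTHER sample for every called position
        if baseline_called:
            cov, alt_n = res_pileup if res_pileup else (
                int(rng.choice(config.coverage_regimes)),
                0,
            )
            pileups[(patient, "resistance")].append(
                PileupCount(chrom=chrom, pos=pos, ref=ref, alt=alt, coverage=cov, alt_reads=alt_n)
            )
        if resistance_called:
            cov, alt_n = base_pileup if base_pileup else (
                int(rng.choice(config.coverage_regimes)),
                0,
            )
            pileups[(patient, "baseline")].append(
                PileupCount(chrom=chrom, pos=pos, ref=ref, alt=alt, coverage=cov, alt_reads=alt_n)
            )
        return key

    # (a) shared clonal mutations, called at both timepoints
    for patient in patients:
        genes = rng.choice(shared_pool, size=config.n_shared_mutations, replace=False)
        for gene in genes:
            add_pair_presence(
                patient, str(gene), chrom=str(rng.integers(1, 23)),
                vaf=float(rng.uniform(0.2, 0.6)),
                baseline_called=True, resistance_called=True,
            )

    # (b) deterministic rescue grid: baseline-only calls on passenger
    # positions with a fixed resistance pileup
    for i, (cov, alt_n) in enumerate(RESCUE_GRID):
        patient = patients[i % len(patients)]
        key = add_pair_presence(
            patient, f"PASSENGER{i}", chrom="5", vaf=0.4,
            baseline_called=True, resistance_called=False,
            res_pileup=(cov, alt_n),
        )
        rescue_cases.append(
            RescueCase(
                patient=patient, key=key, coverage=cov, alt_reads=alt_n,
                rescuable=alt_n >= rescue_threshold(cov),
                target_timepoint="resistance",
            )
        )

    # (c) acquired mutations: each truth gene mutated in >= 2 resistance
    # samples, absent (zero pileup support) at baseline
    acquired_genes = list(config.acquired_mutation_genes)
    for j, gene in enumerate(acquired_genes):
        carriers = patients[2 * j : 2 * j + 2]
        for patient in carriers:
            add_pair_presence(
                patient, gene, chrom="16", vaf=float(rng.uniform(0.15, 0.4)),
                baseline_called=False, resistance_called=True,
            )

    # CNA-only acquired gene in exactly 3 resistance samples (called)
    # and a decoy in exactly 2 (below the CNA-only threshold)
    def add_cna(patient: str, tp: str, gene: str, category: str, length: int,
                run: str = "primary", chrom: str = "9") -> None:
        start = 10_000_000
        segments.append(
            CnaSegment(
                sample_id=f"{patient}-{'T1' if tp == 'baseline' else 'T2'}",
                run=run, chrom=chrom, start=start, end=start + length - 1,
                category=category, genes=(gene,),
            )
        )

    for patient in patients[0:3]:
        add_cna(patient, "resistance", config.acquired_cna_gene, "homozygous_del", 2_000_000)
    for patient in patients[3:5]:
        add_cna(patient, "resistance", config.decoy_cna_gene, "homozygous_del", 2_000_000)

    # (e) focality / substitution constructions on baseline samples
    p0, p1, p2 = patients[0], patients[1], patients[2]
    # 12 Mb high_amp primary replaced by a 2.5 Mb sensitive segment -> kept
    add_cna(p0, "baseline", "ERBB2", "high_amp", 12_000_000, run="primary", chrom="17")
    add_cna(p0, "baseline", "ERBB2", "high_amp", 2_500_000, run="sensitive", chrom="17")
    # 9.9 Mb homozygous deletion -> kept; 10 Mb -> dropped
    add_cna(p1, "baseline", "PTEN", "homozygous_del", 9_900_000, chrom="10")
    add_cna(p2, "baseline", "BRCA2", "homozygous_del", 10_000_000, chrom="13")
    # medium-level amplification: kept on an oncogene, dropped otherwise
    add_cna(p1, "baseline", "CCND1", "medium_amp", 1_500_000, chrom="11")
    add_cna(p2, "baseline", "TP53", "medium_amp", 1_500_000, chrom="17")

    # (d) germline contaminants, present at both timepoints
    unmatched = set(patients[: config.n_unmatched_normal])
    has_matched_normal = {p: p not in unmatched for p in patients}
    for patient in patients:
        n_contaminants = rng.binomial(3, config.germline_rate)
        for _ in range(n_contaminants):
            key = add_pair_presence(
                patient, "GERMLINE_SNP", chrom="1", vaf=0.5,
                baseline_called=True, resistance_called=True, germline=True,
            )
            germline_keys[patient].add(key)

    return PairedVariantCohort(
        patients=patients, calls=calls, pileups=pileups, segments=segments,
        has_matched_normal=has_matched_normal, rescue_cases=rescue_cases,
        acquired_genes=acquired_genes + [config.acquired_cna_gene],
        decoy_genes=[config.decoy_cna_gene],
        germline_keys=germline_keys,
    )


# ---------------------------------------------------------------------------
# Trial outcomes


def gen_trial_outcomes(
    config: Optional[SyntheticCohortConfig] = None, seed: int = 0
) -> pd.DataFrame:
    """Per-cohort Bernoulli confirmed responses as a response-record
    table (columns patient_id, cohort, best_response, confirmed,
    best_change_pct)."""
    config = config or SyntheticCohortConfig()
    rng = _spawn(seed, "trial")
    rows = []
    pid = 0
    for cohort_idx, (n, p) in enumerate(zip(config.cohort_sizes, config.response_probs), start=1):
        for _ in range(n):
            pid += 1
            responder = bool(rng.uniform() < p)
            if responder:
                best = "CR" if rng.uniform() < 0.1 else "PR"
                change = float(rng.uniform(-100.0, -30.0))
            else:
                best = str(rng.choice(["SD", "PD", "NE"], p=[0.5, 0.4, 0.1]))
                if best == "SD":
                    change = float(rng.uniform(-29.0, 19.0))
                elif best == "PD":
                    change = float(rng.uniform(20.0, 60.0))
                else:
                    change = float("nan")
            rows.append(
                {
                    "patient_id": f"S{pid:04d}",
                    "cohort": cohort_idx,
                    "best_response": best,
                    "confirmed": responder,
                    "best_change_pct": change,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cell maps


def _poisson_points(
    rng: np.random.Generator, intensity_per_mm2: float, width_um: float, height_um: float
) -> np.ndarray:
    area_mm2 = width_um * height_um / 1e6
    n = rng.poisson(intensity_per_mm2 * area_mm2)
    pts = np.column_stack([rng.uniform(0, width_um, n), rng.uniform(0, height_um, n)])
    return pts


def gen_cell_maps(
    config: Optional[SyntheticCohortConfig] = None, seed: int = 0
) -> dict[str, dict[str, pd.DataFrame]]:
    """Paired pre/on-treatment cell maps per patient.

    Phenotypes are homogeneous spatial Poisson processes; tumor (CK+)
    cells carry PD-L1 with probability ``pdl1_pos_fraction`` at
    baseline, multiplied by ``on_treatment_ratio`` on treatment (the
    planted effect).  A shared lognormal per-patient abundance
    multiplier induces the between-patient heterogeneity of paired
    biopsies.  Returns {patient: {"baseline": df, "on_treatment": df}}
    with columns x_um, y_um and one boolean column per marker.
    """
    config = config or SyntheticCohortConfig()
    rng = _spawn(seed, "cells")
    out: dict[str, dict[str, pd.DataFrame]] = {}
    w, h = config.map_width_um, config.map_height_um
    for i in range(config.n_pairs):
        patient = f"M{i:02d}"
        mult = float(np.exp(rng.normal(0.0, config.patient_lognorm_sd)))
        out[patient] = {}
        for tp in ("baseline", "on_treatment"):
            pdl1_frac = config.pdl1_pos_fraction
            if tp == "on_treatment":
                pdl1_frac *= config.on_treatment_ratio
            frames = []
            ck = _poisson_points(rng, config.ck_per_mm2 * mult, w, h)
            ck_df = pd.DataFrame(ck, columns=["x_um", "y_um"])
            for m in MARKER_COLUMNS:
                ck_df[m] = False
            ck_df["CK"] = True
            ck_df["PDL1"] = rng.uniform(size=len(ck_df)) < pdl1_frac
            frames.append(ck_df)
            cd3 = _poisson_points(rng, config.cd3_per_mm2 * mult, w, h)
            cd3_df = pd.DataFrame(cd3, columns=["x_um", "y_um"])
            for m in MARKER_COLUMNS:
                cd3_df[m] = False
            cd3_df["CD3"] = True
            u = rng.uniform(size=len(cd3_df))
            cd3_df["CD4"] = u < 0.6
            cd3_df["CD8"] = u >= 0.6
            cd3_df["FoxP3"] = rng.uniform(size=len(cd3_df)) < 0.1
            cd3_df["PD1"] = rng.uniform(size=len(cd3_df)) < 0.2
            frames.append(cd3_df)
            cd68 = _poisson_points(rng, config.cd68_per_mm2 * mult, w, h)
            cd68_df = pd.DataFrame(cd68, columns=["x_um", "y_um"])
            for m in MARKER_COLUMNS:
                cd68_df[m] = False
            cd68_df["CD68"] = True
            cd68_df["PDL1"] = rng.uniform(size=len(cd68_df)) < 0.1
            frames.append(cd68_df)
            df = pd.concat(frames, ignore_index=True)
            out[patient][tp] = df
    return out


MARKER_COLUMNS = ("CD3", "CD4", "CD8", "CD68", "FoxP3", "PD1", "PDL1", "CK")
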