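"""Post-calling rules for paired baseline/resistance tumor biopsies.

Upstream variant calling and copy-number segmentation are consumed as
tables; this module implements the downstream decision rules:

* coverage-dependent mutation rescue between the two timepoints of a
  pair (a mutation called at one timepoint is also called at the other
  when the paired pileup shows enough alt-supporting reads for its
  coverage);
* discarding germline-flagged mutations from both timepoints for
  patients without a matched normal;
* gene-level copy-number event filtering (focal <10 Mb rule, a
  sensitivity-run substitution on driver genes, and the amplification /
  deletion category filter); and
* acquired-alteration calling across a cohort of pairs (gene altered in
  no baseline sample and in at least two resistance samples, three when
  every resistance event is a copy-number event).

Variants travel as MAF-like TSV, pileups and segments as TSV; a toy
driver/oncogene list with the production file schema is packaged for
offline runs.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "VariantCall",
    "PileupCount",
    "CnaSegment",
    "CnaEvent",
    "GeneAlterationMatrix",
    "rescue_threshold",
    "rescue_mutations",
    "discard_unmatched_germline",
    "filter_cna",
    "call_acquired",
    "build_alteration_matrix",
    "load_driver_genes",
    "read_variants_tsv",
    "write_variants_tsv",
    "read_pileup_tsv",
    "read_segments_tsv",
    "split_multiallelic",
    "CNA_CATEGORIES",
]

CNA_CATEGORIES = (
    "high_amp",
    "medium_amp",
    "low_gain",
    "neutral",
    "hemizygous_del",
    "homozygous_del",
)

TIMEPOINTS = ("baseline", "resistance")


class MissingPileupError(KeyError):
    """A retained call has no pileup row in the paired sample."""

    def __init__(self, positions: list[tuple]) -> None:
        self.positions = positions
        super().__init__(f"pileup missing for {len(positions)} position(s): {positions[:5]}")


@dataclass(frozen=True)
class VariantCall:
    """A called point mutation or small indel at one timepoint."""

    sample_id: str
    timepoint: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    vaf: float
    depth: int
    alt_reads: int
    germline_flag: bool = False
    gene: str = ""
    consequence: str = ""
    #: provenance: set to the source timepoint when the call was rescued
    rescued_from: Optional[str] = None

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"timepoint must be one of {TIMEPOINTS}")
        if not (0.0 <= self.vaf <= 1.0):
            raise ValueError("vaf must lie in [0,1]")
        if self.alt_reads > self.depth:
            raise ValueError("alt_reads cannot exceed depth")
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class PileupCount:
    """Read counts at a called position in the paired sample."""

    chrom: str
    pos: int
    ref: str
    alt: str
    coverage: int
    alt_reads: int

    def __post_init__(self) -> None:
        if self.alt_reads > self.coverage:
            raise ValueError("alt_reads cannot exceed coverage")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class CnaSegment:
    """A copy-number segment from one segmentation run.

    ``run`` distinguishes the primary segmentation from the
    higher-sensitivity second run used only on driver genes.
    """

    sample_id: str
    run: str  # "primary" | "sensitive"
    chrom: str
    start: int  # 1-based inclusive
    end: int
    category: str
    genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("segment start must be <= end")
        if self.category not in CNA_CATEGORIES:
            raise ValueError(f"unknown CNA category {self.category!r}")
        if self.run not in ("primary", "sensitive"):
            raise ValueError("run must be 'primary' or 'sensitive'")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class CnaEvent:
    """A gene-level copy-number event surviving the filters."""

    sample_id: str
    gene: str
    category: str
    segment_length: int
    run: str  # run whose estimate was used


def rescue_threshold(coverage: int, at_500: int = 3) -> int:
    """Minimum alt-supporting reads required to rescue a mutation at a
    given pileup coverage: 1 below 100x, 2 from 100x to below 500x, 3
    at 500x and above.

    Coverage exactly 500 falls between the stated bands; the
    conservative choice of 3 reads is applied there (configurable via
    ``at_500``).
    """
    if coverage < 100:
        return 1
    if coverage < 500:
        return 2
    if coverage == 500:
        logger.debug("coverage exactly 500: requiring %d alt reads", at_500)
        return at_500
    return 3


def rescue_mutations(
    calls_a: Sequence[VariantCall],
    pileup_b: Sequence[PileupCount],
    sample_id_b: str,
    timepoint_b: str,
    existing_b: Sequence[VariantCall] = (),
) -> list[VariantCall]:
    """Rescue calls of sample A into paired sample B.

    For each call retained in A, the same mutation is also called in B
    when B's pileup at that position shows at least
    ``rescue_threshold(coverage)`` alt-supporting reads.  Every pileup
    position must cover every call of A.  Calls already present in B
    are skipped; rescued calls carry ``rescued_from`` provenance.
    """
    by_pos = {p.key: p for p in pileup_b}
    missing = [c.key for c in calls_a if c.key not in by_pos]
    if missing:
        raise MissingPileupError(missing)
    existing_keys = {c.key for c in existing_b}
    rescued: list[VariantCall] = []
    for call in calls_a:
        if call.key in existing_keys:
            continue
        pile = by_pos[call.key]
        if pile.alt_reads >= rescue_threshold(pile.coverage):
            rescued.append(
                VariantCall(
                    sample_id=sample_id_b,
                    timepoint=timepoint_b,
                    chrom=call.chrom,
                    pos=call.pos,
                    ref=call.ref,
                    alt=call.alt,
                    vaf=pile.alt_reads / pile.coverage if pile.coverage else 0.0,
                    depth=pile.coverage,
                    alt_reads=pile.alt_reads,
                    germline_flag=call.germline_flag,
                    gene=call.gene,
                    consequence=call.consequence,
                    rescued_from=call.timepoint,
                )
            )
            logger.debug(
                "rescued %s:%d %s>%s into %s (%d/%d reads, from %s)",
                call.chrom, call.pos, call.ref, call.alt,
                sample_id_b, pile.alt_reads, pile.coverage, call.timepoint,
            )
    return rescued


def discard_unmatched_germline(
    calls_baseline: Sequence[VariantCall],
    calls_resistance: Sequence[VariantCall],
    has_matched_normal: bool,
) -> tuple[list[VariantCall], list[VariantCall]]:
    """For patients without a matched normal, drop every mutation
    flagged germline at either timepoint from both timepoints."""
    if has_matched_normal:
        return list(calls_baseline), list(calls_resistance)
    germline_keys = {
        c.key for c in (*calls_baseline, *calls_resistance) if c.germline_flag
    }
    keep_b = [c for c in calls_baseline if c.key not in germline_keys]
    keep_r = [c for c in calls_resistance if c.key not in germline_keys]
    return keep_b, keep_r


def _gene_overlaps(segment: CnaSegment, gene: str) -> bool:
    # Segments carry the overlapping gene symbols directly (any base
    # overlap counts, computed by the segment producer).
    return gene in segment.genes


def filter_cna(
    segments: Sequence[CnaSegment],
    driver_genes: Iterable[str],
    oncogenes: Iterable[str],
    max_segment_bp: int = 10_000_000,
    replace_below_bp: int = 3_000_000,
    replace_ratio: float = 3.0,
    keep_hemizygous_del: bool = False,
) -> list[CnaEvent]:
    """Gene-level CNA events for driver genes after the three filters.

    1. Start from the primary-run segment covering each driver gene;
       substitute the sensitive-run segment when it is shorter than
       3 Mb or more than three times shorter than the primary one.
    2. Drop events whose segment spans 10 Mb or more (focality).
    3. Keep high-level amplifications and homozygous deletions;
       medium-level amplifications only on oncogenes.  Hemizygous
       deletions are excluded by default (``keep_hemizygous_del``
       toggles them in).

    Output order is (sample_id, gene) sorted, independent of input
    segment order.
    """
    drivers = set(driver_genes)
    onco = set(oncogenes)
    primary = [s for s in segments if s.run == "primary"]
    sensitive = [s for s in segments if s.run == "sensitive"]

    events: dict[tuple[str, str], CnaEvent] = {}
    for seg in primary:
        for gene in seg.genes:
            if gene not in drivers:
                continue
            used = seg
            sens_matches = [
                s for s in sensitive if s.sample_id == seg.sample_id and _gene_overlaps(s, gene)
            ]
            if sens_matches:
                sens = min(sens_matches, key=lambda s: s.length)
                if sens.length < replace_below_bp or sens.length * replace_ratio < seg.length:
                    used = sens
            if used.length >= max_segment_bp:
                continue
            cat = used.category
            keep = (
                cat == "high_amp"
                or cat == "homozygous_del"
                or (cat == "medium_amp" and gene in onco)
                or (cat == "hemizygous_del" and keep_hemizygous_del)
            )
            if not keep:
                continue
            key = (seg.sample_id, gene)
            ev = CnaEvent(
                sample_id=seg.sample_id,
                gene=gene,
                category=cat,
                segment_length=used.length,
                run=used.run,
            )
            # deterministic tie-break if several primary segments hit a
            # gene: keep the shorter (more focal) estimate
            if key not in events or ev.segment_length < events[key].segment_length:
                events[key] = ev
    return [events[k] for k in sorted(events)]


@dataclass
class GeneAlterationMatrix:
    """Genes x samples matrix of alteration-event sets.

    Each entry is a set of events, an event being a ("mutation", ...)
    or ("cna", ...) tuple; only events surviving the upstream filters
    belong here.
    """

    genes: list[str]
    samples: list[str]
    entries: dict[tuple[str, str], set] = field(default_factory=dict)

    def add(self, gene: str, sample: str, event: tuple) -> None:
        if gene not in self._gene_set:
            raise KeyError(f"gene {gene!r} outside the matrix universe")
        if sample not in self._sample_set:
            raise KeyError(f"sample {sample!r} outside the matrix universe")
        self.entries.setdefault((gene, sample), set()).add(event)

    def __post_init__(self) -> None:
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample ids must be unique")
        self._gene_set = set(self.genes)
        self._sample_set = set(self.samples)

    def events(self, gene: str, sample: str) -> set:
        return self.entries.get((gene, sample), set())

    def altered_samples(self, gene: str) -> list[str]:
        return [s for s in self.samples if self.events(gene, s)]


def build_alteration_matrix(
    variants: Sequence[VariantCall],
    cna_events: Sequence[CnaEvent],
    genes: Sequence[str],
    samples: Sequence[str],
) -> GeneAlterationMatrix:
    """Assemble a gene-alteration matrix from filtered mutations and
    CNA events; variants on genes outside the universe are ignored."""
    mat = GeneAlterationMatrix(genes=list(genes), samples=list(samples))
    for call in variants:
        if call.gene in mat._gene_set and call.sample_id in mat._sample_set:
            mat.add(call.gene, call.sample_id, ("mutation", call.chrom, call.pos, call.ref, call.alt))
    for ev in cna_events:
        if ev.sample_id in mat._sample_set and ev.gene in mat._gene_set:
            mat.add(ev.gene, ev.sample_id, ("cna", ev.category))
    return mat


def call_acquired(
    baseline: GeneAlterationMatrix,
    resistance: GeneAlterationMatrix,
    min_samples: int = 2,
    min_samples_cna_only: int = 3,
) -> list[str]:
    """Genes with alterations acquired at resistance.

    A gene is reported when (a) no baseline sample carries any
    alteration of it, and (b) at least two resistance samples do —
    raised to three when every resistance event for the gene is a
    copy-number event.
    """
    if set(baseline.genes) != set(resistance.genes):
        raise ValueError("baseline and resistance matrices must share a gene universe")
    acquired: list[str] = []
    for gene in resistance.genes:
        if baseline.altered_samples(gene):
            continue
        altered = resistance.altered_samples(gene)
        if not altered:
            continue
        all_events = set().union(*(resistance.events(gene, s) for s in altered))
        all_cna = all(ev[0] == "cna" for ev in all_events)
        need = min_samples_cna_only if all_cna else min_samples
        if len(altered) >= need:
            acquired.append(gene)
    return acquired


def run_paired_pipeline(
    calls: Mapping[tuple[str, str], Sequence[VariantCall]],
    pileups: Mapping[tuple[str, str], Sequence[PileupCount]],
    segments: Sequence[CnaSegment],
    has_matched_normal: Mapping[str, bool],
    driver_genes: Iterable[str],
    oncogenes: Iterable[str],
    **cna_kwargs,
) -> tuple[list[str], GeneAlterationMatrix, GeneAlterationMatrix]:
    """Full post-calling pipeline over a cohort of baseline/resistance
    pairs: bidirectional rescue, unmatched-germline discard, CNA
    filtering, matrix assembly and acquired-alteration calling.

    ``calls`` and ``pileups`` are keyed by (patient, timepoint); the
    pileup of a sample covers the positions called in its pair.
    Returns (acquired genes, baseline matrix, resistance matrix).
    """
    patients = sorted({p for (p, _) in calls})
    drivers = set(driver_genes)
    all_base: list[VariantCall] = []
    all_res: list[VariantCall] = []
    for patient in patients:
        base = list(calls.get((patient, "baseline"), ()))
        res = list(calls.get((patient, "resistance"), ()))
        res_rescued = rescue_mutations(
            base, pileups.get((patient, "resistance"), ()),
            sample_id_b=f"{patient}-T2", timepoint_b="resistance", existing_b=res,
        )
        base_rescued = rescue_mutations(
            res, pileups.get((patient, "baseline"), ()),
            sample_id_b=f"{patient}-T1", timepoint_b="baseline", existing_b=base,
        )
        base = base + base_rescued
        res = res + res_rescued
        base, res = discard_unmatched_germline(
            base, res, has_matched_normal.get(patient, True)
        )
        all_base.extend(base)
        all_res.extend(res)

    cna_events = filter_cna(segments, drivers, oncogenes, **cna_kwargs)
    base_samples = [f"{p}-T1" for p in patients]
    res_samples = [f"{p}-T2" for p in patients]
    gene_universe = sorted(drivers)
    base_mat = build_alteration_matrix(
        [c for c in all_base if not c.germline_flag],
        [e for e in cna_events if e.sample_id in set(base_samples)],
        gene_universe, base_samples,
    )
    res_mat = build_alteration_matrix(
        [c for c in all_res if not c.germline_flag],
        [e for e in cna_events if e.sample_id in set(res_samples)],
        gene_universe, res_samples,
    )
    return call_acquired(base_mat, res_mat), base_mat, res_mat


# ---------------------------------------------------------------------------
# IO


def load_driver_genes(path=None) -> tuple[set[str], set[str]]:
    """Driver and oncogene symbol sets from a two-column TSV
    (gene, is_oncogene); defaults to the packaged toy list."""
    if path is None:
        ref = importlib.resources.files("trialomics").joinpath("data/driver_genes.tsv")
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    drivers = set(df["gene"].astype(str))
    onco = set(df.loc[df["is_oncogene"].astype(int) == 1, "gene"].astype(str))
    return drivers, onco


_VARIANT_COLS = [
    "sample_id", "timepoint", "chrom", "pos", "ref", "alt", "vaf",
    "depth", "alt_reads", "germline_flag", "gene", "consequence",
]


def split_multiallelic(row: Mapping) -> list[dict]:
    """Split a MAF-like row with comma-separated alt alleles into
    biallelic records (alt reads divided evenly as a convention)."""
    alts = str(row["alt"]).split(",")
    if len(alts) == 1:
        return [dict(row)]
    out = []
    for alt in alts:
        r = dict(row)
        r["alt"] = alt
        r["alt_reads"] = int(row["alt_reads"]) // len(alts)
        r["vaf"] = float(row["vaf"]) / len(alts)
        out.append(r)
    return out


def read_variants_tsv(path) -> list[VariantCall]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    calls = []
    for _, row in df.iterrows():
        for rec in split_multiallelic(row):
            calls.append(
                VariantCall(
                    sample_id=str(rec["sample_id"]),
                    timepoint=str(rec["timepoint"]),
                    chrom=str(rec["chrom"]),
                    pos=int(rec["pos"]),
                    ref=str(rec["ref"]),
                    alt=str(rec["alt"]),
                    vaf=float(rec["vaf"]),
                    depth=int(rec["depth"]),
                    alt_reads=int(rec["alt_reads"]),
                    germline_flag=bool(rec["germline_flag"]),
                    gene=str(rec.get("gene", "") or ""),
                    consequence=str(rec.get("consequence", "") or ""),
                )
            )
    return calls


def write_variants_tsv(calls: Sequence[VariantCall], path) -> None:
    rows = []
    for c in calls:
        rows.append({col: getattr(c, col) for col in _VARIANT_COLS} | {"rescued_from": c.rescued_from or ""})
    pd.DataFrame(rows, columns=_VARIANT_COLS + ["rescued_from"]).to_csv(path, sep="\t", index=False)


def read_pileup_tsv(path) -> list[PileupCount]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        PileupCount(
            chrom=str(r.chrom), pos=int(r.pos), ref=str(r.ref), alt=str(r.alt),
            coverage=int(r.coverage), alt_reads=int(r.alt_reads),
        )
        for r in df.itertuples(index=False)
    ]


def read_segments_tsv(path) -> list[CnaSegment]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    segs = []
    for r in df.itertuples(index=False):
        genes = tuple(g for g in str(r.genes).split(",") if g and g != "nan")
        segs.append(
            CnaSegment(
                sample_id=str(r.sample_id), run=str(r.run), chrom=str(r.chrom),
                start=int(r.start), end=int(r.end), category=str(r.category), genes=genes,
            )
        )
    return segs
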