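"""End-to-end analysis of one CDR/length group.

Reads numbered structures and the loop annotation table, validates chains,
drops incomplete loops, deduplicates predicted loops to non-redundant CDR
sequences (experimental loops keep redundant sequences, which may hold
alternate conformations), superposes everything on the highest-resolution
representative template, computes the batched pairwise RMSD matrix, runs
DBS clustering, profiles and annotates the clusters, embeds with MDS, and
optionally runs the cross-length pass against the next shorter length.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats
from .cluster_profiles import (
    ClusterProfile,
    LogoMatrix,
    Novelty,
    build_profile,
    classify_novelty,
)
from .dbs_clustering import NOISE, SQRT_N_HALF, ClusteringResult, select_clustering
from .geometry import (
    Rejection,
    TemplateChoice,
    align_chain_to_template,
    kabsch_superpose,
    select_template,
    template_from_chain,
)
from .imgt_regions import cdr_range, extract_cdr_loop, validate_chain
from .imgt_regions import IncompleteLoopError
from .length_independence import (
    OriginMatchReport,
    ShmSignatureReport,
    joint_cross_length_matrix,
    origin_cluster_match,
    shm_signature,
)
from .mds_embedding import DEFAULT_LANDMARKS, Embedding2D, embed
from .metrics import DEFAULT_BATCH_SIZE, RMSD, DistanceMatrix, pairwise_matrix
from .types import EXPERIMENTAL, PREDICTED, LoopRecord, NumberedChain

logger = logging.getLogger(__name__)

H3_CAVEAT = (
    "CDRH3 conformational space lacks high-density clusters and informative "
    "central motifs; density-based cluster calls in this region are unreliable."
)


@dataclass
class AnalysisConfig:
    structures_dir: str | Path
    annotations: str | Path
    cdr: str
    imgt_length: int
    out_dir: str | Path | None = None
    metric: str = RMSD
    minpts_rule: str = SQRT_N_HALF
    batch_size: int = DEFAULT_BATCH_SIZE
    max_landmarks: int = DEFAULT_LANDMARKS
    allow_h3: bool = False
    seed: int = 0


@dataclass
class Attrition:
    input_chains: int = 0
    failed_validation: int = 0
    incomplete_loops: int = 0
    wrong_length: int = 0
    redundant_predicted: int = 0
    framework_rejections: int = 0
    clustered: int = 0
    noise: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{k: getattr(self, k) for k in self.__dataclass_fields__}]
        )

    def check_conservation(self) -> bool:
        eliminated = (
            self.failed_validation
            + self.incomplete_loops
            + self.wrong_length
            + self.redundant_predicted
            + self.framework_rejections
        )
        return self.input_chains == self.clustered + self.noise + eliminated


@dataclass
class BatchResult:
    clustering: ClusteringResult
    profiles: list[ClusterProfile]
    embedding: Embedding2D
    loops: dict[str, LoopRecord]
    matrix: DistanceMatrix


@dataclass
class CrossLengthReport:
    matches: list[OriginMatchReport] = field(default_factory=list)
    signatures: dict[int, ShmSignatureReport] = field(default_factory=dict)


@dataclass
class AnalysisResult:
    config: AnalysisConfig
    batches: list[BatchResult]
    attrition: Attrition
    rejections: list[Rejection]
    template: TemplateChoice | None = None
    cross_length: CrossLengthReport | None = None

    @property
    def first(self) -> BatchResult:
        return self.batches[0]


def training_fraction(n_included: int, n_total: int, decimals: int = 1) -> float:
    """Percentage of data points included in a training run, half-up rounded."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_included <= n_total:
        raise ValueError("n_included must be within [0, n_total]")
    pct = Decimal(100 * n_included) / Decimal(n_total)
    quantum = Decimal(1).scaleb(-decimals)
    return float(pct.quantize(quantum, rounding=ROUND_HALF_UP))


def attrition_report(attrition: Attrition) -> pd.DataFrame:
    """Per-stage attrition counters as a one-row table."""
    return attrition.to_frame()


def _read_structures(structures_dir: Path) -> list[NumberedChain]:
    chains: list[NumberedChain] = []
    for path in sorted(structures_dir.glob("*.pdb")):
        chains.extend(io_formats.read_pdb_chains(path))
    return chains


def run_analysis(
    config: AnalysisConfig,
    cross_length_with: "AnalysisResult | str | Path | None" = None,
) -> AnalysisResult:
    """Run the full per-CDR/length pipeline; see the module docstring.

    ``cross_length_with`` is the analysis of the same CDR at IMGT length
    minus one (an in-memory result or a written bundle directory); when
    given, novel clusters are tested for length independence against it.
    """
    if config.cdr == "H3" and not config.allow_h3:
        raise ValueError(f"CDRH3 analysis requires allow_h3=True: {H3_CAVEAT}")
    if config.cdr == "H3":
        logger.warning(H3_CAVEAT)

    annotations = io_formats.read_annotation_table(config.annotations)
    ann_index = {r.key: r for r in annotations}
    chains = _read_structures(Path(config.structures_dir))
    attr = Attrition(input_chains=len(chains))
    rejections: list[Rejection] = []

    # validation + completeness + length filtering; sequences for dedup come
    # from the unaligned chain (alignment does not change them)
    lo, hi = cdr_range(config.cdr)
    candidates: list[tuple[NumberedChain, str, io_formats.AnnotationRecord | None]] = []
    for chain in chains:
        if validate_chain(chain):
            attr.failed_validation += 1
            continue
        record = ann_index.get((chain.structure_id, chain.chain_id, config.cdr))
        if record is not None and not record.cdr_ordered:
            attr.incomplete_loops += 1
            continue
        in_range = [r for r in chain.residues if lo <= r.imgt_number <= hi]
        if len(in_range) != config.imgt_length:
            attr.wrong_length += 1
            continue
        if not all(r.has_backbone() for r in in_range):
            attr.incomplete_loops += 1
            continue
        candidates.append((chain, "".join(r.amino_acid for r in in_range), record))

    # non-redundant predicted sequences (first occurrence); experimental
    # loops keep redundant sequences
    seen: set[str] = set()
    kept: list[tuple[NumberedChain, io_formats.AnnotationRecord | None]] = []
    for chain, seq, record in candidates:
        if record is None:
            if seq in seen:
                attr.redundant_predicted += 1
                continue
            seen.add(seq)
        kept.append((chain, record))

    template_record = select_template(annotations, config.cdr, config.imgt_length)
    template_chain = next(
        (
            c
            for c, _ in kept
            if c.structure_id == template_record.structure_id
            and c.chain_id == template_record.chain_id
        ),
        None,
    )
    if template_chain is None:
        raise ValueError(
            f"template structure {template_record.structure_id}/"
            f"{template_record.chain_id} not among surviving chains"
        )
    template = template_from_chain(
        template_chain, config.cdr, template_record.resolution
    )

    loops: list[LoopRecord] = []
    for chain, record in kept:
        aligned = align_chain_to_template(chain, template, config.cdr)
        if isinstance(aligned, Rejection):
            attr.framework_rejections += 1
            rejections.append(aligned)
            logger.info(
                "rejected %s/%s: %s", aligned.structure_id, aligned.chain_id,
                aligned.reason,
            )
            continue
        try:
            loop = extract_cdr_loop(
                aligned,
                config.cdr,
                loop_id=f"{chain.structure_id}_{chain.chain_id}",
                source=EXPERIMENTAL if record is not None else PREDICTED,
                annotation=record.cluster if record is not None else None,
            )
        except IncompleteLoopError:
            attr.incomplete_loops += 1
            continue
        loops.append(loop)

    if not loops:
        raise ValueError(
            "zero loops survived filtering; attrition: "
            + attr.to_frame().to_string(index=False)
        )

    matrices = pairwise_matrix(loops, config.metric, config.batch_size)
    if isinstance(matrices, DistanceMatrix):
        matrices = [matrices]
    loop_index = {lp.loop_id: lp for lp in loops}

    batches: list[BatchResult] = []
    for matrix in matrices:
        clustering = select_clustering(matrix, config.minpts_rule)
        profiles = []
        for label in clustering.cluster_labels():
            members = [loop_index[i] for i in clustering.members(label)]
            profiles.append(build_profile(label, members, matrix))
        classify_novelty(profiles)
        embedding = embed(matrix, config.max_landmarks)
        attr.clustered += int((clustering.labels != NOISE).sum())
        attr.noise += int((clustering.labels == NOISE).sum())
        batches.append(
            BatchResult(
                clustering=clustering,
                profiles=profiles,
                embedding=embedding,
                loops={i: loop_index[i] for i in matrix.ids},
                matrix=matrix,
            )
        )

    result = AnalysisResult(config, batches, attr, rejections, template=template)
    if cross_length_with is not None:
        result.cross_length = _cross_length_pass(result, cross_length_with)
    if config.out_dir is not None:
        write_bundle(result, Path(config.out_dir))
    return result


# ---------------------------------------------------------------------------
# Cross-length pass
# ---------------------------------------------------------------------------

def _shorter_profiles_and_medoids(
    source: "AnalysisResult | str | Path",
) -> tuple[list[ClusterProfile], list[LoopRecord], np.ndarray | None]:
    if isinstance(source, AnalysisResult):
        batch = source.first
        profiles = batch.profiles
        medoid_loops = [batch.loops[p.medoid_id] for p in profiles]
        anchors = source.template.anchor_ca_coords if source.template else None
        return profiles, medoid_loops, anchors
    return _load_medoids_json(Path(source) / "medoids.json")


def _cross_length_pass(
    result: AnalysisResult, shorter: "AnalysisResult | str | Path"
) -> CrossLengthReport:
    """Test every novel cluster of the first batch for length independence.

    The two analyses live in their own templates' frames; the conserved
    framework anchors are shared across lengths of a CDR, so the shorter
    analysis' medoids are first mapped into the current frame by a Kabsch fit
    of its template anchors onto the current template anchors.
    """
    batch = result.first
    short_profiles, short_medoids, short_anchors = _shorter_profiles_and_medoids(
        shorter
    )
    own_medoids = [batch.loops[p.medoid_id] for p in batch.profiles]
    if not short_medoids or not own_medoids:
        return CrossLengthReport()
    if short_anchors is not None and result.template is not None:
        transform, fit = kabsch_superpose(
            short_anchors, result.template.anchor_ca_coords
        )
        logger.info("cross-length frame fit: %.3f A over template anchors", fit)
        short_medoids = [
            LoopRecord(
                loop_id=lp.loop_id,
                cdr=lp.cdr,
                sequence=lp.sequence,
                imgt_numbers=lp.imgt_numbers,
                backbone=transform.apply(lp.backbone.reshape(-1, 3)).reshape(
                    lp.backbone.shape
                ),
                source=lp.source,
                annotation=lp.annotation,
            )
            for lp in short_medoids
        ]
    D_joint = joint_cross_length_matrix(own_medoids, short_medoids)
    report = CrossLengthReport()
    for profile in batch.profiles:
        if profile.novelty != Novelty.NOVEL_CANDIDATE:
            continue
        others = [p for p in batch.profiles if p.cluster_id != profile.cluster_id]
        match = origin_cluster_match(profile, others, short_profiles, D_joint)
        report.matches.append(match)
        if match.length_independent and match.origin_cluster is not None:
            origin = next(
                p for p in short_profiles if p.cluster_id == match.origin_cluster
            )
            report.signatures[profile.cluster_id] = shm_signature(profile, origin)
    return report


# ---------------------------------------------------------------------------
# Bundle persistence
# ---------------------------------------------------------------------------

def write_bundle(result: AnalysisResult, out_dir: Path) -> None:
    """Write the report bundle: per-loop report, attrition table, DBS
    selection trace, per-cluster FASTA, medoid summaries (for downstream
    cross-length runs) and the cross-length match report when present."""
    out_dir.mkdir(parents=True, exist_ok=True)
    for bi, batch in enumerate(result.batches):
        suffix = "" if len(result.batches) == 1 else f"_batch{bi + 1}"
        io_formats.write_cluster_report(
            batch.clustering,
            batch.profiles,
            out_dir / f"report{suffix}.tsv",
            loops=batch.loops,
            embedding=batch.embedding,
        )
        pd.DataFrame(batch.clustering.trace).to_csv(
            out_dir / f"selection_trace{suffix}.tsv", sep="\t", index=False
        )
        entries = []
        for profile in batch.profiles:
            entries.extend(
                (f"{i}|{profile.cluster_id}", batch.loops[i].sequence)
                for i in profile.member_ids
            )
        io_formats.write_fasta(entries, out_dir / f"clusters{suffix}.fasta")
    result.attrition.to_frame().to_csv(
        out_dir / "attrition.tsv", sep="\t", index=False
    )
    _write_medoids_json(result, out_dir / "medoids.json")
    if result.cross_length is not None:
        _write_cross_length(result.cross_length, out_dir / "cross_length.tsv")


def _write_medoids_json(result: AnalysisResult, path: Path) -> None:
    batch = result.first
    clusters = []
    for profile in batch.profiles:
        loop = batch.loops[profile.medoid_id]
        clusters.append(
            {
                "cluster_id": int(profile.cluster_id),
                "size": int(profile.size),
                "medoid_id": profile.medoid_id,
                "consensus": profile.consensus,
                "novelty": str(profile.novelty),
                "cdr": loop.cdr,
                "sequence": loop.sequence,
                "imgt_numbers": loop.imgt_numbers,
                "backbone": loop.backbone.tolist(),
                "logo_frequencies": profile.logo.frequencies.tolist(),
                "logo_information": profile.logo.information.tolist(),
            }
        )
    payload = {
        "template_anchors": (
            result.template.anchor_ca_coords.tolist() if result.template else None
        ),
        "clusters": clusters,
    }
    path.write_text(json.dumps(payload, indent=1))


def _load_medoids_json(
    path: Path,
) -> tuple[list[ClusterProfile], list[LoopRecord], np.ndarray | None]:
    payload = json.loads(Path(path).read_text())
    anchors = (
        np.array(payload["template_anchors"])
        if payload.get("template_anchors") is not None
        else None
    )
    profiles, medoids = [], []
    for entry in payload["clusters"]:
        loop = LoopRecord(
            loop_id=entry["medoid_id"],
            cdr=entry["cdr"],
            sequence=entry["sequence"],
            imgt_numbers=entry["imgt_numbers"],
            backbone=np.array(entry["backbone"]),
            source=PREDICTED,
        )
        logo = LogoMatrix(
            np.array(entry["logo_frequencies"]),
            np.array(entry["logo_information"]),
        )
        profiles.append(
            ClusterProfile(
                cluster_id=entry["cluster_id"],
                size=entry["size"],
                medoid_id=entry["medoid_id"],
                logo=logo,
                consensus=entry["consensus"],
                novelty=Novelty(entry["novelty"]),
                member_ids=[entry["medoid_id"]],
            )
        )
        medoids.append(loop)
    return profiles, medoids, anchors


def _write_cross_length(report: CrossLengthReport, path: Path) -> None:
    lines = [
        "novel_cluster\tlength_independent\torigin_cluster\tmin_same\tmin_shorter"
        "\tinsertion_position\tmotif_match_fraction"
    ]
    for match in report.matches:
        sig = report.signatures.get(match.novel_cluster)
        lines.append(
            "\t".join(
                [
                    str(match.novel_cluster),
                    str(match.length_independent),
                    "" if match.origin_cluster is None else str(match.origin_cluster),
                    "" if match.min_same is None else f"{match.min_same:.4f}",
                    "" if match.min_shorter is None else f"{match.min_shorter:.4f}",
                    "" if sig is None else str(sig.insertion_position),
                    "" if sig is None else f"{sig.match_fraction:.4f}",
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")
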