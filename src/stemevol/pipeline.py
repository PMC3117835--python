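"""End-to-end orchestration: annotate -> map -> reconstruct -> classify ->
matrices -> profile statistics, with a run manifest for reproducibility.

Each stage consumes plain files (TSV/JSON/FASTA/Newick), so any stage can be
re-run alone; a manifest records input checksums, the full configuration and
per-stage record counts, making runs byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import re
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .ancestral import (
    ContinuousReconstruction,
    parsimony_ancestral_sequences,
    presence_reconstruction,
    squared_change_parsimony,
)
from .errors import (
    EmptyMatrixError,
    NoCallError,
    ParameterError,
    PipelineError,
)
from .events import (
    EventRecord,
    classify_stem_event,
    find_variable_stems,
    tabulate_event_frequencies,
    write_event_log,
)
from .io import (
    StructuralAlignment,
    read_structural_alignment,
    write_matrix_tsv,
)
from .matrices import (
    ANCESTRAL_EXTANT,
    EXTANT_EXTANT,
    count_pair_changes,
    count_single_changes,
    log_odds_transform,
)
from .stems import build_stem_length_table, extract_stems
from .stats import biplot_data, kmeans_stems, pca_stems, wcss_profile
from .tree import PhyloTree, read_newick


@dataclass
class PipelineConfig:
    """All analysis thresholds in one flat record."""

    theta_gap: float = 0.9
    count_bulges: bool = False
    gaps_as_missing: bool = False
    k: int = 3
    seed: int = 0
    restarts: int = 10
    pca_exclude_partial: bool = True
    pca_scale: bool = False
    pseudocount: float = 0.0
    dialect: str = "bracket"


@dataclass
class FamilyResult:
    """In-memory results of one family's full analysis."""

    alignment: StructuralAlignment
    tree: PhyloTree
    stems: object
    table: object
    anc: object
    continuous: dict
    presence: dict
    variable: list
    events: list
    counts: dict  # (mode, comparison) -> SubstitutionCounts or None
    logodds: dict
    clusters: object
    pca: object
    wcss: object


def _norm(name: str) -> str:
    return re.sub(r"[\s_]+", "_", name.strip())


def match_species(alignment: StructuralAlignment, tree: PhyloTree):
    """Prune both inputs to their shared species (exact match after
    whitespace/underscore normalization); warn about the dropped ones."""
    aln_by_norm = {_norm(i): i for i in alignment.ids}
    tree_by_norm = {_norm(n): n for n in tree.leaf_names}
    shared_norm = set(aln_by_norm) & set(tree_by_norm)
    if not shared_norm:
        raise PipelineError(
            "no species shared between alignment and tree; "
            f"alignment has {sorted(alignment.ids)[:5]}..., "
            f"tree has {sorted(tree.leaf_names)[:5]}..."
        )
    dropped_aln = set(alignment.ids) - {aln_by_norm[n] for n in shared_norm}
    dropped_tree = set(tree.leaf_names) - {tree_by_norm[n] for n in shared_norm}
    if dropped_aln or dropped_tree:
        warnings.warn(
            f"pruned {len(dropped_aln)} alignment and {len(dropped_tree)} tree "
            f"species with no counterpart"
        )
    pruned = tree.prune_to({tree_by_norm[n] for n in shared_norm})
    # rename tree leaves to the alignment's spelling
    for leaf in pruned.leaves:
        leaf.name = aln_by_norm[_norm(leaf.name)]
    aln = alignment.subset({aln_by_norm[n] for n in shared_norm})
    return aln, pruned


def run_family(
    alignment: StructuralAlignment,
    tree: PhyloTree,
    config: PipelineConfig | None = None,
) -> FamilyResult:
    """Run every analysis stage on one family, in memory."""
    config = config or PipelineConfig()
    alignment, tree = match_species(alignment, tree)

    stems = extract_stems(alignment.consensus_structure)
    table = build_stem_length_table(alignment, stems, count_bulges=config.count_bulges)
    anc = parsimony_ancestral_sequences(
        tree, alignment, gaps_as_missing=config.gaps_as_missing
    )

    continuous: dict[str, ContinuousReconstruction] = {}
    presence = {}
    for label in table.stem_labels:
        known = table.known_values(label)
        if len(known) == len(tree.leaves):
            continuous[label] = squared_change_parsimony(tree, dict(known))
        elif len(known) >= 2:
            continuous[label] = squared_change_parsimony(
                tree.prune_to(set(known.index)), dict(known)
            )
        obs = {}
        for sp in table.species:
            if table.unknown.loc[sp, label]:
                obs[sp] = "unknown"
            else:
                obs[sp] = "present" if table.lengths.loc[sp, label] > 0 else "absent"
        presence[label] = presence_reconstruction(tree, obs)

    variable = find_variable_stems(table, tree)
    events: list[EventRecord] = []
    for stem_label, clade_id in variable:
        try:
            events.append(
                classify_stem_event(
                    stems.by_label(stem_label),
                    tree.node(clade_id),
                    alignment,
                    anc,
                    theta_gap=config.theta_gap,
                    count_bulges=config.count_bulges,
                )
            )
        except NoCallError as exc:
            warnings.warn(str(exc))

    stem_clades = [
        (stems.by_label(label), tree.node(cid)) for label, cid in variable
    ]
    counts, logodds = {}, {}
    if stem_clades:
        counts[("single", EXTANT_EXTANT)] = count_single_changes(
            alignment, stem_clades, EXTANT_EXTANT
        )
        counts[("single", ANCESTRAL_EXTANT)] = count_single_changes(
            alignment, stem_clades, ANCESTRAL_EXTANT, anc=anc
        )
        counts[("pair", EXTANT_EXTANT)] = count_pair_changes(
            alignment, stem_clades, EXTANT_EXTANT
        )
        counts[("pair", ANCESTRAL_EXTANT)] = count_pair_changes(
            alignment, stem_clades, ANCESTRAL_EXTANT, anc=anc
        )
        for key, c in counts.items():
            try:
                logodds[key] = log_odds_transform(c, pseudocount=config.pseudocount)
            except EmptyMatrixError:
                warnings.warn(f"no events for matrix {key}; skipped")
                logodds[key] = None
    else:
        warnings.warn("no variable stems: matrices skipped")

    clusters = pca = wcss = None
    try:
        clusters = kmeans_stems(
            table, config.k, seed=config.seed, restarts=config.restarts
        )
        wcss = wcss_profile(table, seed=config.seed, restarts=config.restarts)
    except ParameterError as exc:
        warnings.warn(f"clustering skipped: {exc}")
    try:
        pca = pca_stems(
            table,
            exclude_partial=config.pca_exclude_partial,
            scale=config.pca_scale,
        )
    except ParameterError as exc:
        warnings.warn(f"PCA skipped: {exc}")

    return FamilyResult(
        alignment=alignment,
        tree=tree,
        stems=stems,
        table=table,
        anc=anc,
        continuous=continuous,
        presence=presence,
        variable=variable,
        events=events,
        counts=counts,
        logodds=logodds,
        clusters=clusters,
        pca=pca,
        wcss=wcss,
    )


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    alignment_path,
    tree_path,
    outdir,
    config: PipelineConfig | None = None,
) -> Path:
    """File-level pipeline: read inputs, run every stage, write all outputs.

    Emits the stem-length table, reconstructions, event log, frequency
    table, the four substitution matrices with their log-odds transforms,
    PCA/cluster tables and a JSON manifest into ``outdir``.
    """
    config = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    alignment = read_structural_alignment(alignment_path, dialect=config.dialect)
    tree = read_newick(tree_path)
    res = run_family(alignment, tree, config)

    res.stems.to_json(outdir / "stems.json")
    res.table.to_tsv(outdir / "stem_length_table.tsv")
    res.anc.to_fasta(outdir / "ancestral_sequences.fasta", res.tree)
    res.tree.write(outdir / "pruned_tree.nwk", include_internal_names=True)

    recon = {
        "continuous": {
            s: {"values": {str(k): v for k, v in r.values.items()}, "cost": r.cost}
            for s, r in res.continuous.items()
        },
        "presence": {
            s: {"states": {str(k): v for k, v in r.states.items()}, "cost": r.cost}
            for s, r in res.presence.items()
        },
        "ambiguous_columns": {
            str(nid): {str(c + 1): states for c, states in cols.items()}
            for nid, cols in res.anc.ambiguous.items()
        },
        "parsimony_score": res.anc.score,
    }
    (outdir / "reconstructions.json").write_text(json.dumps(recon, indent=1))

    write_event_log(res.events, outdir / "events.json")
    family = res.alignment.family_label or "family"
    freq = tabulate_event_frequencies({family: res.events}) if res.events else None
    if freq is not None:
        freq.to_csv(outdir / "event_frequencies.tsv", sep="\t")

    n_matrices = 0
    for (mode, comparison), c in res.counts.items():
        stembase = f"{mode}_{comparison}"
        write_matrix_tsv(c, outdir / f"counts_{stembase}.tsv")
        lo = res.logodds.get((mode, comparison))
        if lo is not None:
            write_matrix_tsv(lo, outdir / f"logodds_{stembase}.tsv")
            n_matrices += 1

    if res.pca is not None:
        res.pca.scores.round(6).to_csv(outdir / "pca_scores.tsv", sep="\t")
        res.pca.loadings.round(6).to_csv(outdir / "pca_loadings.tsv", sep="\t")
        with open(outdir / "pca_variance.tsv", "w") as fh:
            fh.write("component\tvariance_share\ttop_stem\n")
            for i, (share, top) in enumerate(
                zip(res.pca.explained_variance_ratio, res.pca.top_stems)
            ):
                fh.write(f"PC{i + 1}\t{share:.6f}\t{top}\n")
        clusters = res.clusters
        payload = biplot_data(
            res.pca,
            clusters
            if clusters is not None
            and set(res.pca.scores.index) <= set(clusters.assignments)
            else None,
        )
        (outdir / "biplot.json").write_text(json.dumps(payload, indent=1))
    if res.clusters is not None:
        with open(outdir / "clusters.tsv", "w") as fh:
            fh.write("species\tcluster\n")
            for sp, cl in res.clusters.assignments.items():
                fh.write(f"{sp}\t{cl}\n")
        res.wcss.to_csv(outdir / "wcss_profile.tsv", sep="\t")

    manifest = {
        "version": __version__,
        "inputs": {
            "alignment": {"path": str(alignment_path), "sha256": _sha256(alignment_path)},
            "tree": {"path": str(tree_path), "sha256": _sha256(tree_path)},
        },
        "config": asdict(config),
        "counts": {
            "species": res.alignment.n_sequences,
            "columns": res.alignment.n_columns,
            "stems": len(res.stems),
            "variable_stem_clades": len(res.variable),
            "events": len(res.events),
            "matrices": n_matrices,
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return outdir
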