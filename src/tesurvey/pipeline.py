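"""End-to-end orchestration: simulate/load -> mine -> build -> classify ->
census/landscape -> phylogeny/HT, from a single validated configuration.

The survey protocol's thresholds (2 kb flanks, 80% identity / 40% coverage
census, >=300 aa intact ORF, TA TSD) are the named defaults, so a minimal
configuration runs the protocol as published.  Every stage writes its
tables into the output directory and the run log records seeds, thresholds
and per-stage counts, so summary numbers are regenerable from the bundle.
"""
from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import census as census_mod
from . import elements as elements_mod
from . import mining as mining_mod
from .classify import check_signature, classify_protein, is_intact
from .ht import (HTCluster, HTReport, HTThresholds, ClusterElement,
                 find_candidate_clusters, ht_verdict)
from .references import load_references
from .scenarios import demo_tree
from .synthetic import (GenomeRecord, HostTree, SyntheticTruth, default_spec,
                        evolve_control_genes, plant_elements,
                        plant_family_on_tree, simulate_host_tree,
                        synthesize_genomes, write_control_genes,
                        write_genomes)

__all__ = ["Thresholds", "PipelineConfig", "ReportBundle", "validate_config",
           "run_pipeline", "ConfigError"]


class ConfigError(ValueError):
    """Configuration invalid; ``errors`` lists every offending field."""

    def __init__(self, errors: list[str]):
        super().__init__("; ".join(errors))
        self.errors = errors


@dataclass
class Thresholds:
    flank_bp: int = 2000
    min_identity: float = 80.0        # census identity threshold
    min_coverage: float = 40.0        # census coverage threshold
    min_orf_aa: int = 300
    min_report_score: float = 75.0    # mining raw-score cutoff
    mining_min_identity: float | None = None   # optional 80%-identity filter
    max_gap: int = 500                # hit-merging gap
    min_arm: int = 10
    min_arm_identity: float = 85.0
    tir_window: int = 2100
    ht_identity: float = 80.0
    ht_age: float = 100.0
    alpha: float = 0.05
    bootstrap_reps: int = 100

    def ht(self) -> HTThresholds:
        return HTThresholds(identity=self.ht_identity, age=self.ht_age,
                            alpha=self.alpha)


_RANGES = {
    "flank_bp": (0, 100_000), "min_identity": (0, 100),
    "min_coverage": (0, 100), "min_orf_aa": (50, 10_000),
    "min_report_score": (0, 1e6), "max_gap": (0, 1_000_000),
    "min_arm": (5, 1000), "min_arm_identity": (50, 100),
    "tir_window": (100, 100_000), "ht_identity": (0, 100),
    "ht_age": (0, 10_000), "alpha": (0, 1), "bootstrap_reps": (10, 10_000),
}


@dataclass
class PipelineConfig:
    seed: int
    output_dir: str
    thresholds: Thresholds
    synthetic: dict | None = None
    inputs: dict | None = None


@dataclass
class ReportBundle:
    outdir: str
    tree: HostTree
    genomes: list[GenomeRecord]
    truth: SyntheticTruth | None
    hits: list
    loci: list
    models: list
    classification: list[dict]
    census: census_mod.CensusTable
    landscapes: dict
    ht_reports: list[HTReport]
    run_log: dict
    files: list[str] = field(default_factory=list)

    def checksum(self) -> str:
        """Digest over the bundle's written report files."""
        h = hashlib.sha256()
        for path in sorted(self.files):
            h.update(Path(path).name.encode())
            h.update(Path(path).read_bytes())
        return h.hexdigest()


def validate_config(source) -> PipelineConfig:
    """Load + normalise a configuration; raises ConfigError listing every
    out-of-range value by field name."""
    if isinstance(source, (str, os.PathLike)):
        try:
            with open(source) as fh:
                raw = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError([f"cannot parse configuration: {exc}"])
        except OSError as exc:
            raise ConfigError([f"cannot read configuration: {exc}"])
    else:
        raw = dict(source)
    if not isinstance(raw, dict):
        raise ConfigError(["configuration must be a mapping"])
    errors: list[str] = []
    thr_raw = raw.get("thresholds", {}) or {}
    thr = Thresholds()
    for key, value in thr_raw.items():
        if not hasattr(thr, key):
            errors.append(f"thresholds.{key}: unknown field")
            continue
        setattr(thr, key, value)
    for key, (lo, hi) in _RANGES.items():
        v = getattr(thr, key)
        if v is not None and not (lo <= v <= hi):
            errors.append(f"thresholds.{key}: {v} outside [{lo}, {hi}]")
    synthetic = raw.get("synthetic")
    inputs = raw.get("inputs")
    if (synthetic is None) == (inputs is None):
        errors.append("exactly one of 'synthetic' or 'inputs' must be set")
    if synthetic:
        for fam in synthetic.get("families", []):
            name = fam.get("family", "?")
            frac = fam.get("defective_fraction", 0.0)
            if not 0 <= frac <= 1:
                errors.append(f"families[{name}].defective_fraction: {frac} "
                              "outside [0, 1]")
    if errors:
        raise ConfigError(errors)
    return PipelineConfig(
        seed=int(raw.get("seed", 0)),
        output_dir=str(raw.get("output_dir", "tesurvey_out")),
        thresholds=thr, synthetic=synthetic, inputs=inputs)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: PipelineConfig, log: dict):
    syn = cfg.synthetic
    master = np.random.default_rng(cfg.seed)
    if syn.get("tree") == "demo":
        tree = demo_tree()
    elif "newick" in syn:
        tree = HostTree.from_newick(syn["newick"])
    else:
        tree = simulate_host_tree(int(syn.get("n_species", 5)),
                                  float(syn.get("root_age", 110.0)),
                                  int(master.integers(2**31)))
    genomes = synthesize_genomes(tree, int(syn.get("genome_length", 300_000)),
                                 float(syn.get("gc", 0.35)),
                                 int(master.integers(2**31)))
    truth = SyntheticTruth(species=tree.labels)
    for fam_cfg in syn.get("families", []):
        spec = default_spec(fam_cfg["family"])
        species = fam_cfg.get("species", "all")
        species = tree.labels if species == "all" else list(species)
        mode = fam_cfg.get("mode", "tree")
        seed = int(master.integers(2**31))
        if mode == "tree":
            ht_events = [(e["donor"], e["recipient"],
                          float(e["residual_divergence"]))
                         for e in fam_cfg.get("ht_events", [])]
            plant_family_on_tree(
                genomes, tree, spec,
                copies_per_species=int(fam_cfg.get("copies_per_species", 2)),
                rate=float(fam_cfg.get("rate", 0.002)),
                within_divergence=float(fam_cfg.get("within_divergence",
                                                    0.01)),
                defective_fraction=float(fam_cfg.get("defective_fraction",
                                                     0.0)),
                defective_mode=fam_cfg.get("defective_mode", "frameshift"),
                seed=seed, species=species, truth=truth,
                ht_events=ht_events)
        else:
            subset = [g for g in genomes if g.species in species]
            plant_elements(
                subset, spec,
                copies_per_species=int(fam_cfg.get("copies_per_species", 2)),
                divergence=fam_cfg.get("divergence", 0.05),
                defective_fraction=float(fam_cfg.get("defective_fraction",
                                                     0.0)),
                defective_mode=fam_cfg.get("defective_mode", "mixed"),
                seed=seed, truth=truth)
    genes_cfg = syn.get("control_genes")
    genes = {}
    if genes_cfg:
        genes = evolve_control_genes(
            tree, int(genes_cfg.get("n_genes", 20)),
            int(genes_cfg.get("length_bp", 1500)),
            float(genes_cfg.get("rate", 0.002)),
            int(master.integers(2**31)))
    log["simulate"] = {"species": tree.labels,
                       "planted_copies": len(truth.records),
                       "ht_events": len(truth.ht_events),
                       "control_genes": len(genes)}
    return tree, genomes, truth, genes


def _load_fasta(path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = ""
            elif name is not None:
                seqs[name] += line.strip().upper()
    return seqs


def _stage_load(cfg: PipelineConfig, log: dict):
    inp = cfg.inputs
    missing = [k for k in ("genomes", "host_tree") if k not in inp]
    if missing:
        raise ConfigError([f"inputs.{k}: required" for k in missing])
    genomes = []
    for path in inp["genomes"]:
        if not os.path.exists(path):
            raise ConfigError([f"inputs.genomes: {path} not found"])
        species = Path(path).stem
        contigs = {name.split("|")[-1]: seq
                   for name, seq in _load_fasta(path).items()}
        genomes.append(GenomeRecord(species, contigs))
    tree = HostTree.from_newick(Path(inp["host_tree"]).read_text())
    genes: dict[str, dict[str, str]] = {}
    for path in inp.get("control_genes", []):
        genes[Path(path).stem] = _load_fasta(path)
    log["load"] = {"species": [g.species for g in genomes],
                   "control_genes": len(genes)}
    return tree, genomes, None, genes


def run_pipeline(config: PipelineConfig | dict | str,
                 stop_after: str = "ht") -> ReportBundle:
    """Execute the survey; idempotent for a fixed seed.

    ``stop_after`` truncates the run after a stage ("simulate", "mining",
    "elements", "census", "ht"); because every stage is deterministic
    given the seed, a truncated run is byte-identical to the prefix of a
    full run, so per-stage CLI commands compose exactly.
    """
    order = ["simulate", "mining", "elements", "census", "ht"]
    if stop_after not in order:
        raise ValueError(f"unknown stage: {stop_after}")
    stop_idx = order.index(stop_after)

    def partial(stage: str, **kw) -> ReportBundle | None:
        if order.index(stage) < stop_idx:
            return None
        defaults = dict(hits=[], loci=[], models=[], classification=[],
                        census=census_mod.CensusTable.from_counts({}),
                        landscapes={}, ht_reports=[])
        defaults.update(kw)
        log_path = outdir / "run_log.json"
        with open(log_path, "w") as fh:
            json.dump({**log, "stopped_after": stage,
                       "files": sorted(Path(f).name for f in files)},
                      fh, indent=1, default=str)
        files.append(str(log_path))
        return ReportBundle(outdir=str(outdir), tree=tree, genomes=genomes,
                            truth=truth, run_log=log, files=files,
                            **defaults)

    cfg = (config if isinstance(config, PipelineConfig)
           else validate_config(config))
    thr = cfg.thresholds
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "genomes").mkdir(exist_ok=True)
    log: dict = {"seed": cfg.seed, "thresholds": asdict(thr)}
    files: list[str] = []

    if cfg.synthetic is not None:
        tree, genomes, truth, genes = _stage_simulate(cfg, log)
        files += write_genomes(genomes, outdir / "genomes")
        truth_tsv = outdir / "truth.tsv"
        truth.to_tsv(truth_tsv)
        truth.to_json(outdir / "truth.json")
        files += [str(truth_tsv), str(outdir / "truth.json")]
        if genes:
            (outdir / "control_genes").mkdir(exist_ok=True)
            files += write_control_genes(genes, outdir / "control_genes")
    else:
        tree, genomes, truth, genes = _stage_load(cfg, log)
    tree_path = outdir / "host_tree.nwk"
    tree_path.write_text(tree.newick() + "\n")
    files.append(str(tree_path))
    done = partial("simulate")
    if done:
        return done

    references = load_references()

    # --- mining ---
    hits, loci = [], []
    for genome in genomes:
        g_hits = mining_mod.search_genome(
            references, genome, min_report_score=thr.min_report_score,
            min_identity=thr.mining_min_identity)
        hits += g_hits
        loci += mining_mod.merge_hits(g_hits, max_gap_bp=thr.max_gap)
    hits_path = outdir / "hits.tsv"
    mining_mod.write_hits_tsv(hits, hits_path)
    files.append(str(hits_path))
    loci_path = outdir / "loci.json"
    with open(loci_path, "w") as fh:
        json.dump([{"locus_id": l.locus_id, "species": l.species,
                    "contig": l.contig, "start": l.start + 1,
                    "end": l.end, "strand": l.strand, "score": l.score,
                    "queries": l.query_ids} for l in loci], fh, indent=1)
    files.append(str(loci_path))
    log["mining"] = {"hits": len(hits), "loci": len(loci)}
    done = partial("mining", hits=hits, loci=loci)
    if done:
        return done

    # --- element building + classification ---
    by_species = {g.species: g for g in genomes}
    models = []
    classification = []
    for locus in loci:
        genome = by_species[locus.species]
        cand = mining_mod.extract_with_flanks(genome, locus, thr.flank_bp)
        tirs = elements_mod.find_tirs(
            cand, min_arm=thr.min_arm,
            min_arm_identity=thr.min_arm_identity,
            window=thr.tir_window, n_best=6)
        model = elements_mod.call_boundaries(
            cand, tirs, element_id=f"{locus.species}_L{locus.locus_id}",
            min_orf_aa=thr.min_orf_aa)
        label = None
        homology = (0.0, None)    # best (score, family) over tried spans
        if model.orf is not None:
            label, triad = classify_protein(model.orf.protein, references)
            if triad.reference is not None:
                homology = max(homology, (triad.score,
                                          triad.reference.family))
        else:
            # defective copies: try the few longest sub-threshold reading
            # spans of the element itself (partial transposase segments)
            target = model.sequence or cand.seq
            for orf_any in elements_mod.find_all_orfs(target, min_aa=100)[:3]:
                label, triad = classify_protein(orf_any.protein, references)
                if triad.reference is not None:
                    homology = max(homology, (triad.score,
                                              triad.reference.family))
                if label is not None:
                    break
        notes = ";".join(label.notes) if label else ""
        if label is not None:
            family = label.family
        elif homology[0] >= 100.0:
            # a frameshift splits the triad across reading spans, but the
            # family is still evident from transposase homology
            family = homology[1]
            notes = "homology-only"
        else:
            family = "unclassified"
        model.family = family
        sig = check_signature(model, family)
        intact = is_intact(model) and (model.orf.length_aa >=
                                       thr.min_orf_aa)
        models.append(model)
        classification.append({
            "element_id": model.element_id, "species": model.species,
            "contig": model.contig,
            "start": model.start, "end": model.end,
            "strand": model.strand,
            "label": label.label if label else "",
            "family": family,
            "notes": notes,
            "signature": sig, "intact": bool(intact),
            "orf_aa": model.orf.length_aa if model.orf else 0,
            "tir_len": model.tir.arm_len if model.tir else 0,
            "tsd": model.tsd.status if model.tsd else "indeterminate",
        })
    cls_path = outdir / "classification.tsv"
    _write_table(classification, cls_path)
    files.append(str(cls_path))
    elems_fa = outdir / "elements.fna"
    with open(elems_fa, "w") as fh:
        for m in models:
            if m.sequence:
                fh.write(f">{m.element_id} {m.family}\n{m.sequence}\n")
    files.append(str(elems_fa))
    orf_fa = outdir / "elements.faa"
    with open(orf_fa, "w") as fh:
        for m in models:
            if m.orf is not None:
                fh.write(f">{m.element_id} {m.family}\n{m.orf.protein}\n")
    files.append(str(orf_fa))
    log["elements"] = {"models": len(models),
                       "boundary_called": sum(m.boundary_called
                                              for m in models),
                       "orf_only": sum(not m.boundary_called
                                       for m in models)}
    done = partial("elements", hits=hits, loci=loci, models=models,
                   classification=classification)
    if done:
        return done

    # --- census + landscapes ---
    counts: dict[tuple[str, str], tuple[int, int]] = {}
    landscapes: dict[tuple[str, str], census_mod.DivergenceProfile] = {}
    families = sorted({m.family for m in models
                       if m.family and m.family != "unclassified"
                       and not m.family.startswith("novel:")})
    for sp in sorted(by_species):
        genome = by_species[sp]
        for family in families:
            copies = [m.sequence for m in models
                      if m.species == sp and m.family == family
                      and m.sequence]
            if not copies:
                counts[(sp, family)] = (0, 0)
                continue
            consensus = elements_mod.build_consensus(copies)
            records = census_mod.count_copies(
                genome, consensus, min_identity=thr.min_identity,
                min_coverage=thr.min_coverage)
            intact_models = [m for m in models
                             if m.species == sp and m.family == family
                             and m.boundary_called and is_intact(m)]
            n_intact = 0
            for rec in records:
                hit = any(m.contig == rec.contig
                          and rec.start < m.end and m.start < rec.end
                          for m in intact_models)
                rec.intact = hit
                n_intact += hit
            counts[(sp, family)] = (len(records), n_intact)
            landscapes[(sp, family)] = census_mod.divergence_landscape(
                records, genome.length, family=family, species=sp)
    census_table = census_mod.CensusTable.from_counts(
        counts, species=sorted(by_species))
    census_path = outdir / "census.tsv"
    census_table.to_tsv(census_path)
    files.append(str(census_path))
    (outdir / "landscapes").mkdir(exist_ok=True)
    for (sp, family), prof in landscapes.items():
        p = outdir / "landscapes" / f"{sp}_{family}.tsv"
        prof.to_tsv(p)
        files.append(str(p))
    log["census"] = {f"{sp}:{fam}": c for (sp, fam), c in counts.items()}
    done = partial("census", hits=hits, loci=loci, models=models,
                   classification=classification, census=census_table,
                   landscapes=landscapes)
    if done:
        return done

    # --- family trees and distance matrices ---
    from .phylo import align_nucleotides, distance_matrix, neighbor_joining
    (outdir / "trees").mkdir(exist_ok=True)
    for family in families:
        elems = [(m.element_id, m.sequence) for m in models
                 if m.family == family and m.sequence]
        if len(elems) < 3:
            continue
        dm = distance_matrix(align_nucleotides(elems), model="k2p")
        dpath = outdir / f"distances_{family}.tsv"
        dm.to_tsv(dpath)
        files.append(str(dpath))
        if not dm.saturated:
            tpath = outdir / "trees" / f"{family}.nwk"
            tpath.write_text(neighbor_joining(dm).newick + "\n")
            files.append(str(tpath))

    # --- horizontal transfer ---
    ht_reports: list[HTReport] = []
    if genes:
        for family in families:
            elems = [ClusterElement(m.element_id, m.species, m.sequence)
                     for m in models
                     if m.family == family and m.sequence]
            if len({e.species for e in elems}) < 2 or len(elems) < 2:
                continue
            clusters = find_candidate_clusters(elems, tree, thr.ht(),
                                               family=family)
            for cl in clusters:
                ht_reports.append(ht_verdict(cl, tree, census_table,
                                             genes, thr.ht()))
        ht_path = outdir / "ht_reports.json"
        with open(ht_path, "w") as fh:
            fh.write("[" + ",\n".join(r.to_json() for r in ht_reports)
                     + "]\n")
        files.append(str(ht_path))
        summary_path = outdir / "ht_summary.txt"
        with open(summary_path, "w") as fh:
            if not ht_reports:
                fh.write("no candidate horizontal-transfer clusters\n")
            for r in ht_reports:
                fh.write(
                    f"{r.cluster_family}: members {', '.join(r.members)} "
                    f"(species {', '.join(r.member_species)})\n"
                    f"  identity {r.identity_mean:.2f}% +/- "
                    f"{r.identity_sd:.2f}%  RF {r.rf_distance}  "
                    f"patchy={'yes' if r.condition_patchy else 'no'} "
                    f"(absent: {', '.join(r.absent_species) or '-'})\n"
                    f"  distance test p="
                    f"{r.distance_test.p_value if r.distance_test.p_value is not None else 'NA'}"
                    f"  verdict: {r.verdict}\n")
        files.append(str(summary_path))
        # pairwise identity matrices per family with >= 2 elements
        from .phylo import identity_matrix
        for family in families:
            elems = [(m.element_id, m.sequence) for m in models
                     if m.family == family and m.sequence]
            if len(elems) < 2:
                continue
            labels, mat, _mean, _sd = identity_matrix(elems)
            ipath = outdir / f"identity_{family}.tsv"
            with open(ipath, "w") as fh:
                fh.write("element\t" + "\t".join(labels) + "\n")
                for i, lab in enumerate(labels):
                    fh.write(lab + "\t" + "\t".join(
                        f"{v:.2f}" for v in mat[i]) + "\n")
            files.append(str(ipath))
        log["ht"] = {"clusters": len(ht_reports),
                     "supported": sum(r.verdict == "HT-supported"
                                      for r in ht_reports)}
    else:
        log["ht"] = "not run (no control genes)"

    log_path = outdir / "run_log.json"
    with open(log_path, "w") as fh:
        json.dump({**log, "files": sorted(Path(f).name for f in files)},
                  fh, indent=1, default=str)
    files.append(str(log_path))
    return ReportBundle(
        outdir=str(outdir), tree=tree, genomes=genomes, truth=truth,
        hits=hits, loci=loci, models=models, classification=classification,
        census=census_table, landscapes=landscapes, ht_reports=ht_reports,
        run_log=log, files=files)


def _write_table(rows: list[dict], path) -> None:
    if not rows:
        Path(path).write_text("")
        return
    cols = list(rows[0])
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(row[c]) for c in cols) + "\n")


def _fmt(v) -> str:
    if isinstance(v, bool):
        return str(int(v))
    if isinstance(v, float):
        return f"{v:.4f}"
    if v is None:
        return ""
    return str(v)
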