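"""End-to-end workflow: simulate a clone library, analyze it, report.

``run_simulate`` writes a self-contained input directory (FASTA files,
locus annotation, ground-truth table, manifest).  ``run_analyze`` consumes
such a directory — or real data laid out the same way — and emits the
figure/table-style outputs of the clone-heterogeneity analysis:

* ``fig3_summary.tsv``       mean/max distances, four analytical settings;
* ``table2_correlations.tsv`` locus-independence correlation tables;
* ``fig4_histograms.tsv``    pairwise distance histograms per locus/source;
* ``fig4_summary.json``      threshold exceedance + spurious OTU counts;
* ``attribution.tsv``        per-read species attribution;
* ``fig5_spectrum.tsv``      SNP records vs the two type strains;
* ``spectrum_summary.json``  per-locus spectrum tallies;
* ``trees/*.nwk``            UPGMA (per locus, whole ITS, concatenated) and
  NJ (concatenated) trees with bootstrap supports.

Runs are deterministic: a fixed config and seed give byte-identical outputs
(log timestamps aside), and the exact config used is written into the
output directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .consensus import add_consensus, load_clone_pairs, reverse_complement
from .correlation import correlation_table, locus_distance_profiles
from .distances import (
    anchored_codes,
    distance_set,
    four_setting_summary,
    mcl_distance_matrix,
    p_distance_matrix,
)
from .identification import (
    ThresholdSet,
    attribute_read,
    attribute_read_nearest,
    distance_histogram,
    spurious_otu_count,
    threshold_exceedance,
)
from .seqio import (
    AlignmentScoring,
    read_annotation,
    read_fasta,
    write_annotation,
    write_fasta,
)
from .simulate import (
    SimConfig,
    simulate_clone_reads,
    simulate_repeat_array,
    simulate_sanger_reference,
)
from .spectrum import build_spectrum
from .trees import as_newick, bootstrap_support

logger = logging.getLogger("ribovar.pipeline")


@dataclasses.dataclass
class RunConfig:
    """Analysis-stage configuration (validated before any stage runs)."""

    input_dir: str = "."
    out_dir: str = "analysis"
    consensus_policy: str = "reference_biased"
    metric: str = "tn93_mcl"
    original_strand: str = "fwd"
    threshold_its: float = 0.0159
    threshold_lsu: float = 0.01
    threshold_whole_its: float = 0.0069
    bootstrap_nj: int = 1000
    bootstrap_upgma: int = 100
    attribution_mode: str = "threshold"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.consensus_policy not in ("iupac", "fwd_wins", "reference_biased"):
            raise ValueError(f"bad consensus policy {self.consensus_policy!r}")
        if self.metric not in ("p", "tn93_mcl"):
            raise ValueError(f"bad metric {self.metric!r}")
        if self.original_strand not in ("fwd", "rev"):
            raise ValueError(f"bad strand {self.original_strand!r}")
        if self.bootstrap_nj < 1 or self.bootstrap_upgma < 1:
            raise ValueError("bootstrap replicate counts must be >= 1")

    def thresholds(self) -> ThresholdSet:
        return ThresholdSet(
            LSU=self.threshold_lsu,
            ITS1=self.threshold_its,
            ITS2=self.threshold_its,
            s58=self.threshold_its,
            whole_its=self.threshold_whole_its,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_simulate(cfg: SimConfig, out_dir, force: bool = False) -> Path:
    """Generate a full simulated input directory from a seeded config."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"output dir {out} is not empty (use force)")
    out.mkdir(parents=True, exist_ok=True)

    sim = simulate_repeat_array(cfg)
    reference, secondary = simulate_sanger_reference(sim)
    clones = simulate_clone_reads(sim, cfg)

    write_fasta(sim.copy_sequences(), out / "copies.fasta")
    write_fasta([c.fwd for c in clones], out / "clones_F.fasta")
    # reverse reads are emitted as raw reverse-strand sequences
    write_fasta([reverse_complement(c.rev) for c in clones], out / "clones_R.fasta")
    write_fasta([reference], out / "reference.fasta")
    write_fasta([sim.species_A_canonical], out / "typeA.fasta")
    write_fasta([sim.species_B_canonical], out / "typeB.fasta")
    write_annotation(sim.annotation.with_reference(reference.id), out / "annotation.tsv")
    truth = sim.truth.copy()
    truth["carriers"] = truth["carriers"].map(lambda t: ",".join(map(str, t)))
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    pd.DataFrame({
        "clone_id": [c.clone_id for c in clones],
        "source_copy": [c.source_copy for c in clones],
    }).to_csv(out / "clone_sources.tsv", sep="\t", index=False)
    (out / "secondary_peaks.txt").write_text(
        "\n".join(map(str, secondary)) + ("\n" if secondary else "")
    )

    files = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
    manifest = {
        "tool": "ribovar",
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "checksums": {name: _sha256(out / name) for name in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out


def _load_inputs(input_dir: Path):
    ref = read_fasta(input_dir / "reference.fasta")[0]
    type_a = read_fasta(input_dir / "typeA.fasta")[0]
    type_b = read_fasta(input_dir / "typeB.fasta")[0]
    ann = read_annotation(input_dir / "annotation.tsv").with_reference(ref.id)
    clones = load_clone_pairs(input_dir / "clones_F.fasta", input_dir / "clones_R.fasta")
    return ref, type_a, type_b, ann, clones


def run_analyze(config: RunConfig, force: bool = False) -> Path:
    """Run the full analysis workflow; any stage failure aborts with the
    stage name, leaving prior outputs plus a ``.partial`` marker."""
    input_dir = Path(config.input_dir)
    out = Path(config.out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"output dir {out} is not empty (use force)")
    out.mkdir(parents=True, exist_ok=True)
    (out / "trees").mkdir(exist_ok=True)
    marker = out / ".partial"
    marker.write_text("analysis in progress\n")

    fh = logging.FileHandler(out / "analysis.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("ribovar")
    root.addHandler(fh)
    root.setLevel(logging.INFO)

    stage = "load_inputs"
    try:
        ref, type_a, type_b, ann, clones = _load_inputs(input_dir)
        scoring = AlignmentScoring()
        thresholds = config.thresholds()
        (out / "config.json").write_text(json.dumps(config.to_dict(), indent=2) + "\n")

        stage = "consensus"
        logger.info("building consensus (policy=%s) for %d clones",
                    config.consensus_policy, len(clones))
        add_consensus(clones, policy=config.consensus_policy, ref=ref, scoring=scoring)

        stage = "distances"
        fig3 = four_setting_summary(
            ref, clones, ann, metric=config.metric,
            original_strand=config.original_strand, scoring=scoring,
        )
        fig3.to_csv(out / "fig3_summary.tsv", sep="\t", index=False)

        stage = "correlation"
        blocks = []
        for source in ("consensus", "original"):
            profiles = locus_distance_profiles(
                ref, clones, ann, source=source, metric="p",
                original_strand=config.original_strand, scoring=scoring,
            )
            table, pairs = correlation_table(profiles, on_degenerate="nan")
            pairs.insert(0, "source", source)
            blocks.append(pairs)
        pd.concat(blocks, ignore_index=True).to_csv(
            out / "table2_correlations.tsv", sep="\t", index=False
        )

        stage = "identification"
        _run_identification(out, ref, type_a, type_b, ann, clones, config, thresholds, scoring)

        stage = "spectrum"
        ann_a = ann.with_reference(type_a.id)
        report = build_spectrum(
            [c.consensus for c in clones], type_a, type_b, ann_a, scoring=scoring
        )
        report.to_tsv(out / "fig5_spectrum.tsv")
        summary = report.summary()
        summary["_typestrain_diff_positions"] = {
            k: list(v) for k, v in report.typestrain_diffs.items()
        }
        (out / "spectrum_summary.json").write_text(json.dumps(summary, indent=2) + "\n")

        stage = "trees"
        _run_trees(out, ref, type_a, type_b, ann, clones, config, scoring)
    except Exception as exc:
        logger.error("stage %s failed: %s", stage, exc)
        root.removeHandler(fh)
        fh.close()
        raise RuntimeError(f"analysis stage {stage!r} failed: {exc}") from exc
    marker.unlink()
    root.removeHandler(fh)
    fh.close()
    return out


def _locus_blocks(ann, ref):
    """(locus, slice) pairs including the composite whole-ITS barcode."""
    blocks = [(locus, [np.arange(s, e)]) for locus, s, e in ann.intervals]
    its = [np.arange(s, e) for locus, s, e in ann.intervals if locus != "LSU"]
    blocks.append(("whole_ITS", its))
    return [(locus, np.concatenate(parts)) for locus, parts in blocks]


def _run_identification(out, ref, type_a, type_b, ann, clones, config, thresholds, scoring):
    cons = anchored_codes(ref, [c.consensus for c in clones], scoring)
    orig = anchored_codes(ref, [c.original(config.original_strand) for c in clones], scoring)
    type_rows = anchored_codes(ref, [type_a, type_b], scoring)
    ids = [c.clone_id for c in clones]
    n = len(clones)

    histograms = []
    summary = {}
    attribution = []
    for locus, cols in _locus_blocks(ann, ref):
        t = thresholds.for_locus(locus)
        summary[locus] = {"threshold": t}
        for source, mat in (("consensus", cons), ("original", orig)):
            dm_builder = p_distance_matrix if config.metric == "p" else mcl_distance_matrix
            dm = dm_builder(mat[:, cols], ids=ids, locus=locus, setting=f"pairwise_{source}")
            hist = distance_histogram(dm, bins=20)
            hist.insert(0, "source", source)
            hist.insert(0, "locus", locus)
            histograms.append(hist)
            summary[locus][source] = {
                "exceedance": threshold_exceedance(dm, t),
                "spurious_otus": spurious_otu_count(dm, t),
                "mean": float(np.nanmean(dm.condensed)),
                "max": float(np.nanmax(dm.condensed)),
            }
        # single-read attribution (original sequences, as in a metagenomics run)
        block = np.vstack([mat_row[cols][None, :] for mat_row in type_rows] + [orig[:, cols]])
        pairs_a = [(0, k + 2) for k in range(n)]
        pairs_b = [(1, k + 2) for k in range(n)]
        d_a = distance_set(block, pairs_a, metric=config.metric)
        d_b = distance_set(block, pairs_b, metric=config.metric)
        for read_id, da, db in zip(ids, d_a, d_b):
            call = (attribute_read(da, db, t) if config.attribution_mode == "threshold"
                    else attribute_read_nearest(da, db))
            attribution.append({
                "read_id": read_id, "locus": locus,
                "distance_to_A": da, "distance_to_B": db,
                "threshold": t, "call": call,
            })
        att = [a for a in attribution if a["locus"] == locus]
        for call_name in ("A", "B", "ambiguous_both", "novel_neither"):
            summary[locus][f"pct_{call_name}"] = 100.0 * sum(
                1 for a in att if a["call"] == call_name
            ) / len(att)

    pd.concat(histograms, ignore_index=True).to_csv(
        out / "fig4_histograms.tsv", sep="\t", index=False
    )
    pd.DataFrame(attribution).to_csv(out / "attribution.tsv", sep="\t", index=False)
    (out / "fig4_summary.json").write_text(json.dumps(summary, indent=2) + "\n")


def _run_trees(out, ref, type_a, type_b, ann, clones, config, scoring):
    cons = anchored_codes(ref, [c.consensus for c in clones], scoring)
    type_rows = anchored_codes(ref, [type_a, type_b], scoring)
    codes = np.vstack([cons, type_rows])
    ids = [c.clone_id for c in clones] + [type_a.id, type_b.id]

    for locus, cols in _locus_blocks(ann, ref) + [("concat", np.arange(codes.shape[1]))]:
        block = codes[:, cols]
        tree = bootstrap_support(
            block, ids=ids, builder="upgma", metric=config.metric,
            n_reps=config.bootstrap_upgma, seed=config.seed,
        )
        (out / "trees" / f"upgma_{locus}.nwk").write_text(as_newick(tree))
    nj = bootstrap_support(
        codes, ids=ids, builder="nj", metric=config.metric,
        n_reps=config.bootstrap_nj, seed=config.seed,
    )
    (out / "trees" / "nj_concat.nwk").write_text(as_newick(nj))


def run_report(analysis_dir) -> str:
    """Assemble a human-readable summary from a completed analysis dir."""
    adir = Path(analysis_dir)
    needed = ["fig3_summary.tsv", "table2_correlations.tsv", "fig4_summary.json",
              "spectrum_summary.json", "config.json"]
    missing = [n for n in needed if not (adir / n).exists()]
    if missing or (adir / ".partial").exists():
        raise FileNotFoundError(
            f"analysis dir incomplete; missing {missing or ['.partial marker present']}"
        )
    fig3 = pd.read_csv(adir / "fig3_summary.tsv", sep="\t")
    corr = pd.read_csv(adir / "table2_correlations.tsv", sep="\t")
    fig4 = json.loads((adir / "fig4_summary.json").read_text())
    spec = json.loads((adir / "spectrum_summary.json").read_text())

    lines = ["# Clone-library heterogeneity report", ""]
    lines.append("## Distances from the reference (four settings)")
    for _, row in fig3.iterrows():
        lines.append(
            f"- {row.locus:>4} {row.setting}: mean {100 * row['mean']:.3f}%, "
            f"max {100 * row['max']:.3f}% (n={row.n})"
        )
    lines.append("")
    lines.append("## Species-threshold exceedance (pairwise clone distances)")
    any_het = False
    for locus, info in fig4.items():
        if locus.startswith("_"):
            continue
        for source in ("consensus", "original"):
            ex = info[source]["exceedance"]
            if ex > 0:
                any_het = True
            lines.append(
                f"- {locus} ({source}): {100 * ex:.2f}% of pairs beyond the "
                f"{100 * info['threshold']:.2f}% threshold; "
                f"{info[source]['spurious_otus']} spurious OTU(s)"
            )
    lines.append("")
    lines.append("## SNP spectrum vs the two type strains")
    n_records = 0
    for locus, info in spec.items():
        if locus.startswith("_"):
            continue
        n_records += (info["high_vs_A"] + info["low_vs_A"]
                      + info["high_vs_B"] + info["low_vs_B"])
        lines.append(
            f"- {locus}: {info['typestrain_diffs']} type-strain difference(s); "
            f"vs A {info['high_vs_A']} high / {info['low_vs_A']} low; "
            f"vs B {info['high_vs_B']} high / {info['low_vs_B']} low; "
            f"{info['intermediate']} intermediate"
        )
    if n_records == 0:
        lines.append("- no heterogeneity detected")
    lines.append("")
    lines.append("## Locus independence")
    max_r = corr["r"].abs().max()
    lines.append(
        f"- max |r| across locus pairs and sources: {max_r:.3f} "
        f"({'consistent with independent variation' if max_r < 0.5 else 'possible coupling'})"
    )
    if not any_het and n_records == 0:
        lines.append("")
        lines.append("Overall: no heterogeneity detected among the cloned copies.")
    text = "\n".join(lines) + "\n"
    (adir / "report.md").write_text(text)
    return text
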