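"""One-command pipeline: simulate -> periodicity -> classify -> phr -> rdna.

Each enabled stage writes its artifacts under the output directory and
contributes counts and parameters to a machine-readable report
(``report.json``). Rerunning with the same config and seed reproduces
byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from . import io as sio
from .config import PipelineConfig
from .errors import InputError, SatarchError
from .periodicity import dominant_period, ntr_spectrum, segment_monomers
from .phr import find_phrs, phr_network
from .rdna import (
    allocate_array_copies,
    call_cdrs,
    classify_activity,
    compare_sex_copy_number,
    estimate_total_copies,
    find_rdna_units,
)
from .satclass import annotate_satellite_arrays, classify_monomers, train_profiles
from .synthetic import (
    RdnaFeature,
    SyntheticTruth,
    TrackSpec,
    TruthRecord,
    default_genome_plan,
    simulate_depth_track,
    synthesize_genome,
)

__all__ = ["run_pipeline"]


def _block(truth: SyntheticTruth, chrom: str, feature_class: str):
    for r in truth.records:
        if r.sequence_name == chrom and r.feature_class == feature_class:
            return r
    return None


def _stage_simulate(cfg: PipelineConfig, outdir: Path, report: dict):
    sim = cfg["simulate"]
    plan = default_genome_plan(seed=cfg["seed"], scale=sim["scale"])
    seqs, truth = synthesize_genome(plan)
    # plant a hypomethylated dip (candidate kinetochore site) inside the
    # chr17 active alpha array so the CDR caller has something to find
    alpha = _block(truth, "chr17", "alpha_array")
    if alpha is not None and alpha.end - alpha.start >= 30000:
        mid = (alpha.start + alpha.end) // 2
        truth.records.append(
            TruthRecord("chr17", mid - 6000, mid + 6000, "cdr", "+")
        )
        truth.sort()
    spec = TrackSpec(
        mean_depth=sim["mean_depth"],
        noise_sd=sim["noise_sd"],
        bin_size=sim["bin_size"],
        methylation_states=(
            ("cdr", 0.1),
            ("rdna_coding", sim["coding_methylation"]),
            ("rdna_igs", sim["igs_methylation"]),
            ("alpha_array", 0.8),
        ),
    )
    depth, meth = simulate_depth_track(
        seqs, truth, spec, sim["rdna_total_copies"], seed=cfg["seed"]
    )
    sio.write_fasta(seqs, outdir / "genome.fa")
    sio.write_truth_bed(truth, outdir / "truth.bed")
    sio.write_track(depth, outdir / "depth.tsv")
    sio.write_track(meth, outdir / "meth.tsv")
    report["simulate"] = {
        "n_chromosomes": len(seqs),
        "genome_bp": sum(len(s) for s in seqs.values()),
        "n_truth_records": len(truth.records),
        "rdna_total_copies": sim["rdna_total_copies"],
    }
    return plan, seqs, truth, depth, meth


def _stage_periodicity(cfg, outdir: Path, report: dict, seqs, truth):
    pcfg = cfg["periodicity"]
    results = {}
    monomers_by_chrom = {}
    for chrom, label in [
        ("chr17", "alpha_array"),
        ("chr19", "alpha_array"),
        ("chr20", "alpha_array"),
        ("chr17", "subterminal_array"),
        ("chrX", "hor_array"),
    ]:
        block = _block(truth, chrom, label)
        if block is None:
            continue
        arr = seqs[chrom][block.start : block.end]
        spectrum = ntr_spectrum(arr, k=pcfg["k"], max_period=pcfg["max_period"])
        top = dominant_period(spectrum, 3)
        sio.write_spectrum_tsv(spectrum, outdir / f"spectrum_{chrom}_{label}.tsv")
        results[f"{chrom}:{label}"] = {"dominant_period": top[0][0] if top else None}
        if label in ("alpha_array", "hor_array") and top:
            # monomer-scale segmentation: dimers/HORs decompose at ~170 bp
            period = top[0][0]
            while period > 260 and period % 2 == 0:
                period //= 2
            mons = segment_monomers(
                arr, period, k=pcfg["k"], sequence_name=chrom
            )
            monomers_by_chrom.setdefault(chrom, []).extend(
                m.__class__(m.sequence_name, m.start + block.start,
                            m.end + block.start, m.strand, m.sequence)
                for m in mons
            )
            results[f"{chrom}:{label}"]["n_monomers"] = len(mons)
    report["periodicity"] = results
    return monomers_by_chrom


def _stage_classify(cfg, outdir: Path, report: dict, seqs, truth, monomers_by_chrom):
    ccfg = cfg["classify"]
    # training monomers come from the planted per-monomer truth (up to 50
    # per family), emulating a curated monomer library
    families: dict[str, list[str]] = {}
    block_classes = {
        "alpha_array", "subterminal_array", "hor_array", "rdna_array",
        "phr_shared", "cdr", "rdna_unit", "rdna_coding", "rdna_igs",
    }
    for r in truth.records:
        if r.feature_class in block_classes or r.feature_class.startswith("spacer"):
            continue
        fam = families.setdefault(r.feature_class, [])
        if len(fam) < 50:
            fam.append(seqs[r.sequence_name][r.start : r.end])
    profiles = train_profiles(families)
    # monomer family -> array-level group (an alpha dimer alternates S3/S4
    # monomers; array merging operates on the shared group label)
    group_of: dict[str, str] = {}
    for r in truth.records:
        if r.feature_class not in families:
            continue
        for b in truth.records:
            if (
                b.sequence_name == r.sequence_name
                and b.feature_class in ("alpha_array", "subterminal_array", "hor_array")
                and b.start <= r.start
                and r.end <= b.end
            ):
                group_of.setdefault(r.feature_class, b.feature_class)
    anchor_of = {  # one family reference per array group fixes the cut phase
        group: profiles.profiles[fam].reference
        for fam, group in sorted(group_of.items(), key=lambda kv: kv[0], reverse=True)
    }
    all_assignments = []
    windows = {}
    for chrom in sorted(seqs):
        for label in ("alpha_array", "hor_array"):
            block = _block(truth, chrom, label)
            if block is None:
                continue
            windows[chrom] = (block.start, block.end)
            arr = seqs[chrom][block.start : block.end]
            period = len(anchor_of[label])
            mons = segment_monomers(
                arr, period, sequence_name=chrom, phase_anchor=anchor_of[label]
            )
            mons = [
                m.__class__(m.sequence_name, m.start + block.start,
                            m.end + block.start, m.strand, m.sequence)
                for m in mons
            ]
            assignments = classify_monomers(
                mons, profiles, min_margin=ccfg["min_margin"]
            )
            all_assignments.extend(assignments)
    grouped = [
        a.__class__(a.monomer, group_of.get(a.family, a.family), a.score,
                    a.margin, a.strand)
        for a in all_assignments
    ]
    # smooth isolated interruptions: a single discordant call flanked by the
    # same group on both sides takes the flanking group (boundary-slip calls
    # would otherwise fragment one array into many)
    for i in range(1, len(grouped) - 1):
        prev, cur, nxt = grouped[i - 1], grouped[i], grouped[i + 1]
        if (
            prev.sequence_name == cur.sequence_name == nxt.sequence_name
            and prev.family == nxt.family != cur.family
        ):
            grouped[i] = cur.__class__(
                cur.monomer, prev.family, cur.score, cur.margin, cur.strand
            )
    arrays = annotate_satellite_arrays(
        grouped,
        min_array_monomers=ccfg["min_array_monomers"],
        max_gap=ccfg["max_gap"],
        centromere_windows=windows,
    )
    sio.write_monomers_bed(all_assignments, outdir / "monomers.bed")
    sio.write_annotations_bed(arrays, outdir / "arrays.bed")
    n_ambiguous = sum(1 for a in all_assignments if a.family == "ambiguous")
    report["classify"] = {
        "n_monomers_classified": len(all_assignments),
        "n_ambiguous": n_ambiguous,
        "n_arrays": len(arrays),
        "n_active": sum(1 for a in arrays if a.layer == "active"),
    }
    return arrays


def _stage_phr(cfg, outdir: Path, report: dict, seqs):
    pcfg = cfg["phr"]
    acro = {"chr17", "chr19", "chr20"}
    pairs = [("chr17", "chr19"), ("chr17", "chr20"), ("chr19", "chr20")]
    all_phrs = []
    for a, b in pairs:
        if a not in seqs or b not in seqs:
            continue
        all_phrs.extend(
            find_phrs(
                seqs[a], seqs[b],
                window=pcfg["window"], step=pcfg["step"],
                min_identity=pcfg["min_identity"],
                min_span=pcfg["min_span"],
                names=(a, b),
            )
        )
    network = phr_network(all_phrs, acrocentric_names=acro)
    sio.write_phrs_bedpe(all_phrs, outdir / "phrs.bedpe")
    sio.write_network_tsv(network, outdir / "phr_network.tsv")
    report["phr"] = {
        "n_phrs": len(all_phrs),
        "n_edges": len(network.edges),
        "shared_bp": sum(bp for _, _, bp, _ in network.edges),
    }
    return all_phrs


def _stage_rdna(cfg, outdir: Path, report: dict, plan, seqs, truth, depth, meth):
    rcfg = cfg["rdna"]
    model = None
    for chrom_plan in plan.chromosomes:
        for feat in chrom_plan.features:
            if isinstance(feat, RdnaFeature):
                model = feat.model
    rdna_block = _block(truth, "chr17", "rdna_array")
    units = []
    if model is not None and rdna_block is not None:
        region = seqs["chr17"][rdna_block.start : rdna_block.end]
        units = [
            u.__class__(
                "chr17", u.start + rdna_block.start, u.end + rdna_block.start,
                u.orientation, u.intact, u.insertions,
                u.coding_start + rdna_block.start,
                u.coding_end + rdna_block.start,
            )
            for u in find_rdna_units(
                region, (model.coding, model.igs), sequence_name="chr17"
            )
        ]
    total = None
    allocation = None
    if rdna_block is not None:
        total = estimate_total_copies(
            depth,
            ("chr17", rdna_block.start, rdna_block.end),
            ("chr20", 0, len(seqs["chr20"])),
            min_bins=10,
        )
        allocation = allocate_array_copies(total, {"chr17_rdna": 1.0})
    summaries = classify_activity(
        meth, units, threshold=rcfg["activity_threshold"]
    ) if units else []
    alpha = _block(truth, "chr17", "alpha_array")
    cdrs = []
    if alpha is not None:
        cdrs = call_cdrs(
            meth,
            ("chr17", alpha.start, alpha.end),
            min_cdr_span=rcfg["min_cdr_span"],
            dip_factor=rcfg["dip_factor"],
        )
    rng = np.random.default_rng(cfg["seed"] + 7)
    cohort = [(f"m{i}", "M", float(rng.normal(500, 20))) for i in range(15)] + [
        (f"f{i}", "F", float(rng.normal(400, 20))) for i in range(15)
    ]
    stat, pval, means = compare_sex_copy_number(
        cohort, n_permutations=999, seed=cfg["seed"] + 11
    )
    with open(outdir / "rdna_summary.tsv", "w") as fh:
        fh.write("array_id\tcoding_mean\tigs_mean\tstate\n")
        for s in summaries:
            fh.write(f"{s.array_id}\t{s.coding_mean:.4f}\t{s.igs_mean:.4f}\t{s.state}\n")
    with open(outdir / "cdrs.bed", "w") as fh:
        for c in cdrs:
            fh.write(
                f"{c.sequence_name}\t{c.start}\t{c.end}\t"
                f"{c.mean_methylation_inside:.4f}\t{c.flank_mean:.4f}\n"
            )
    report["rdna"] = {
        "n_units": len(units),
        "n_intact": sum(1 for u in units if u.intact),
        "estimated_total_copies": round(total, 2) if total is not None else None,
        "allocated": [list(a) for a in allocation.arrays] if allocation else None,
        "n_active_arrays": sum(1 for s in summaries if s.state == "active"),
        "n_cdrs": len(cdrs),
        "sex_test": {
            "statistic": round(stat, 4),
            "p_value": round(pval, 6),
            **{k: round(v, 2) for k, v in means.items()},
        },
    }


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the enabled stages in order and write all artifacts.

    Returns the report dict (also written to ``<outdir>/report.json``).
    Stage failures abort with the stage name and cause.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = config["stages"]
    report: dict = {"seed": config["seed"], "parameters": dict(config)}
    plan = seqs = truth = depth = meth = None
    try:
        if stages["simulate"]:
            plan, seqs, truth, depth, meth = _stage_simulate(config, outdir, report)
        else:
            fasta = config["inputs"]["fasta"]
            if not fasta:
                raise InputError(
                    "simulate stage disabled and no input FASTA configured"
                )
            seqs = sio.read_fasta(fasta)
            truth_bed = config["inputs"]["truth_bed"]
            truth = sio.read_truth_bed(truth_bed) if truth_bed else SyntheticTruth()
    except SatarchError as exc:
        raise SatarchError(f"stage 'simulate' failed: {exc}") from exc

    monomers_by_chrom: dict = {}
    for name, runner in [
        ("periodicity", lambda: _stage_periodicity(config, outdir, report, seqs, truth)),
        ("classify", lambda: _stage_classify(
            config, outdir, report, seqs, truth, monomers_by_chrom)),
        ("phr", lambda: _stage_phr(config, outdir, report, seqs)),
    ]:
        if not stages[name]:
            continue
        try:
            result = runner()
        except SatarchError as exc:
            raise SatarchError(f"stage '{name}' failed: {exc}") from exc
        if name == "periodicity":
            monomers_by_chrom.update(result)
    if stages["rdna"] and plan is not None:
        try:
            _stage_rdna(config, outdir, report, plan, seqs, truth, depth, meth)
        except SatarchError as exc:
            raise SatarchError(f"stage 'rdna' failed: {exc}") from exc

    payload = json.dumps(report, indent=2, sort_keys=True)
    (outdir / "report.json").write_text(payload + "\n")
    report["report_checksum"] = hashlib.sha256(payload.encode()).hexdigest()
    return report
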