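"""End-to-end driver: simulate → scan → MSY → palindrome → Ks dating →
small RNA → methylation → expression, with one config, one seed, and a
reproducibility manifest.

Stage outputs land in per-stage subdirectories of the output directory;
the manifest records the config hash, seed, per-stage outputs with their
content hashes and wall times.  Re-running with an identical config and
seed reproduces identical output hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bsa, coverage, divergence, formats, methylome, palindrome, \
    simdata, smallrna, expression

log = logging.getLogger("slrkit")

__version__ = "0.1.0"


@dataclass
class ScanParams:
    """Scan geometry for the pipeline run.

    The defaults are scaled to the toy genome (10-kb tiling windows so a
    candidate boundary resolves to one step, genome-wide envelope and a
    two-window minimum span so single-window permutation noise is never
    called; see docs/methods.md).  For a full-size genome use
    window=1_000_000, step=10_000, per-window envelope.
    """

    window: int = 10_000
    step: int = 10_000
    n_permutations: int = 1000
    level: float = 0.95
    min_depth: int = 10
    min_sites: int = 10
    genome_wide: bool = True
    min_candidate_len: int = 15_000


def scenario_from_dict(d: dict) -> simdata.ScenarioConfig:
    d = dict(d)
    if "slr" in d:
        d["slr"] = (str(d["slr"][0]), int(d["slr"][1]), int(d["slr"][2]))
    if "msy_segments" in d:
        d["msy_segments"] = tuple((int(s), int(e)) for s, e in d["msy_segments"])
    if "inversion" in d and d["inversion"] is not None:
        d["inversion"] = (int(d["inversion"][0]), int(d["inversion"][1]))
    if "smallrna_len_probs" in d:
        d["smallrna_len_probs"] = {int(k): float(v)
                                   for k, v in d["smallrna_len_probs"].items()}
    if "ks_targets" in d:
        d["ks_targets"] = tuple(float(k) for k in d["ks_targets"])
    if "expr" in d:
        expr = dict(d["expr"])
        if "tissues" in expr:
            expr["tissues"] = tuple(expr["tissues"])
        d["expr"] = simdata.ExpressionDesign(**expr)
    return simdata.ScenarioConfig(**d)


def load_scenario(path) -> simdata.ScenarioConfig:
    with open(path) as fh:
        return scenario_from_dict(yaml.safe_load(fh) or {})


def _config_hash(config: simdata.ScenarioConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str = __version__
    stages: dict = field(default_factory=dict)    # stage -> {outputs, seconds}

    @property
    def output_hash(self) -> str:
        items = sorted((p, h) for st in self.stages.values()
                       for p, h in st["outputs"].items())
        return hashlib.sha256(json.dumps(items).encode()).hexdigest()[:16]

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["output_hash"] = self.output_hash
        return json.dumps(d, indent=2, sort_keys=True)


class _Stage:
    def __init__(self, manifest: RunManifest, name: str, outdir: Path):
        self.manifest = manifest
        self.name = name
        self.dir = outdir / name
        self.dir.mkdir(parents=True, exist_ok=True)
        self._t0 = None

    def __enter__(self):
        self._t0 = time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb):
        seconds = round(time.perf_counter() - self._t0, 3)
        outputs = {str(p.relative_to(self.dir.parent)): _file_hash(p)
                   for p in sorted(self.dir.rglob("*")) if p.is_file()}
        self.manifest.stages[self.name] = {
            "outputs": outputs, "seconds": seconds,
            "failed": exc_type is not None,
        }
        log.info("stage %-10s %6.2fs  %d output file(s)%s", self.name,
                 seconds, len(outputs), "  FAILED" if exc_type else "")
        return False


def run_all(config: simdata.ScenarioConfig, outdir,
            scan: ScanParams | None = None,
            compare_truth: bool = True) -> RunManifest:
    """Run every stage on a fresh synthetic scenario.

    Returns the manifest; also writes ``manifest.json`` and a Markdown
    ``report.md`` (with truth-comparison sections when ``compare_truth``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scan = scan or ScanParams()
    manifest = RunManifest(_config_hash(config), config.seed)
    report: list[str] = [f"# slrkit run report\n",
                         f"- config hash: {manifest.config_hash}",
                         f"- seed: {config.seed}\n"]

    # ---- simulate ---------------------------------------------------------
    with _Stage(manifest, "simulate", outdir) as st:
        refs, truth = simdata.simulate_genome(config)
        mref = simdata.male_reference(refs, config)
        fref = simdata.female_reference(refs, config)
        formats.write_fasta(mref, st.dir / "male_reference.fa")
        formats.write_fasta(fref, st.dir / "female_reference.fa")
        calls = simdata.simulate_pools(refs, truth, config)
        formats.write_pool_calls_tsv(calls, st.dir / "pool_calls.tsv")
        formats.write_pool_calls_vcf(
            calls, st.dir / "pool_calls.vcf",
            {c: len(s) for c, s in mref.items()})
        formats.write_bed([truth.slr], st.dir / "truth_slr.bed")
        formats.write_bed(truth.msy, st.dir / "truth_msy.bed")

    chrom_lengths = {c: len(s) for c, s in mref.items()}

    # ---- ΔSNP-index scan --------------------------------------------------
    with _Stage(manifest, "bsa", outdir) as st:
        sites = bsa.site_snp_index(calls, scan.min_depth)
        windows = bsa.permutation_envelope(
            sites, scan.window, scan.step, scan.n_permutations, scan.level,
            seed=np.random.default_rng(config.seed + 1),
            min_sites=scan.min_sites, chrom_lengths=chrom_lengths,
            genome_wide=scan.genome_wide)
        formats.write_windows(windows, st.dir / "windows.tsv")
        candidates = bsa.call_candidates(windows, step=scan.step)
        slr_call = bsa.select_slr(candidates,
                                  min_len=scan.min_candidate_len)
        formats.write_bed([c.interval for c in candidates],
                          st.dir / "candidates.bed",
                          names=[c.direction for c in candidates])
        if slr_call:
            formats.write_bed([slr_call.interval], st.dir / "slr.bed")
    report.append("## Sex-linked region scan")
    if slr_call:
        iv = slr_call.interval
        report.append(f"- selected SLR: {iv.chrom}:{iv.start}-{iv.end} "
                      f"({iv.length_kb} kb, {slr_call.direction})")
    else:
        report.append("- no SLR found")
    if compare_truth and slr_call:
        report.append(f"- truth: {truth.slr.chrom}:{truth.slr.start}-"
                      f"{truth.slr.end}; boundary errors "
                      f"{abs(slr_call.interval.start - truth.slr.start)} / "
                      f"{abs(slr_call.interval.end - truth.slr.end)} bp")
    report.append("")

    # ---- coverage / MSY ---------------------------------------------------
    with _Stage(manifest, "msy", outdir) as st:
        depth_f, depth_m = simdata.simulate_depth(refs, truth, config)
        formats.write_tsv(depth_f, st.dir / "depth_female.tsv")
        formats.write_tsv(depth_m, st.dir / "depth_male.tsv")
        exclude = [truth.slr] if compare_truth else \
            ([slr_call.interval] if slr_call else [])
        bins = coverage.binned_depth(depth_f, depth_m, exclude=exclude)
        msy_calls = coverage.call_msy(bins)
        formats.write_bed(msy_calls, st.dir / "msy.bed")
    report.append("## Male-specific regions")
    for iv in msy_calls:
        report.append(f"- {iv.chrom}:{iv.start}-{iv.end} ({iv.length_kb} kb)")
    if compare_truth:
        hit = sum(any(t.overlaps(c) for c in msy_calls) for t in truth.msy)
        report.append(f"- truth recall: {hit}/{len(truth.msy)}")
    report.append("")

    # ---- palindrome arms --------------------------------------------------
    with _Stage(manifest, "palindrome", outdir) as st:
        y_seq = refs[f"{config.slr_chrom}_Y"]
        slr_seq = y_seq[truth.slr.start:truth.slr.end]
        arms = palindrome.find_inverted_repeats(
            slr_seq, chrom=config.slr_chrom)
        rows = [{
            "arm1_start": p.arm1.start + truth.slr.start,
            "arm1_end": p.arm1.end + truth.slr.start,
            "arm2_start": p.arm2.start + truth.slr.start,
            "arm2_end": p.arm2.end + truth.slr.start,
            "identity": round(p.identity, 4), "spacer": p.spacer,
        } for p in arms]
        formats.write_tsv(pd.DataFrame(rows), st.dir / "arm_pairs.tsv")
    report.append("## Palindrome arms")
    report.append(f"- {len(arms)} arm pair(s) found")
    if compare_truth:
        ok = 0
        for a1, a2 in truth.arm_pairs:
            for p in arms:
                if (GI := formats.GenomeInterval)(
                        config.slr_chrom, p.arm1.start + truth.slr.start,
                        p.arm1.end + truth.slr.start).overlaps(a1) and \
                   GI(config.slr_chrom, p.arm2.start + truth.slr.start,
                      p.arm2.end + truth.slr.start).overlaps(a2):
                    ok += 1
                    break
        report.append(f"- truth arm pairs recovered: {ok}/{len(truth.arm_pairs)}")
    report.append("")

    # ---- Ks dating --------------------------------------------------------
    with _Stage(manifest, "ks", outdir) as st:
        pairs = simdata.simulate_gene_pairs(
            config.ks_targets, config.cds_length, config.rng("gene_pairs"))
        rows = []
        for sp in pairs:
            cp = divergence.CodingPair(sp.id_x, sp.id_y, sp.cds_x, sp.cds_y)
            ka, ks = divergence.ng86(cp)
            age = divergence.time_from_ks(ks)
            stratum = divergence.classify_stratum(ks)
            rows.append({"id_x": sp.id_x, "id_y": sp.id_y,
                         "target_ks": sp.target_ks, "ka": round(ka, 5),
                         "ks": round(ks, 5), "age_my": round(age, 2),
                         "stratum": stratum.label})
        ks_table = pd.DataFrame(rows)
        formats.write_tsv(ks_table, st.dir / "ks_pairs.tsv")
    report.append("## Ks dating")
    for r in rows:
        report.append(f"- {r['id_x']}/{r['id_y']}: Ks {r['ks']} "
                      f"(target {r['target_ks']}), {r['age_my']} My, "
                      f"{r['stratum']} stratum")
    report.append("")

    # ---- small RNA --------------------------------------------------------
    with _Stage(manifest, "smallrna", outdir) as st:
        segs = {name: seq for name, (iv, seq)
                in truth.smallrna_segments.items()}
        reads = simdata.simulate_smallrna(config, segs)
        formats.write_fasta(zip(reads["read_id"], reads["seq"]),
                            st.dir / "reads.fa")
        assigned, _ = smallrna.map_reads(reads, segs)
        profiles = smallrna.size_profile(assigned, sorted(segs))
        prof_rows = [{"segment": p.segment, "total": p.total,
                      "fraction_24": (round(p.fraction_24, 4)
                                      if p.fraction_24 is not None else ""),
                      "flagged": p.flagged} for p in profiles]
        formats.write_tsv(pd.DataFrame(prof_rows), st.dir / "profiles.tsv")
        hp12 = smallrna.hairpin_pairing(segs["S1"], segs["S2"])
        hp3l2 = smallrna.hairpin_pairing(segs["S3"], segs["L2"])
    report.append("## Small RNA")
    for r in prof_rows:
        report.append(f"- {r['segment']}: {r['total']} reads, 24-nt fraction "
                      f"{r['fraction_24']}, flagged={r['flagged']}")
    report.append(f"- hairpin S1-S2: identity {hp12[0]:.3f}, "
                  f"paired={hp12[1]}")
    report.append(f"- hairpin S3-L2: identity {hp3l2[0]:.3f}, "
                  f"paired={hp3l2[1]}\n")

    # ---- methylation ------------------------------------------------------
    with _Stage(manifest, "methyl", outdir) as st:
        records, genes, truth_dmrs = simdata.simulate_methylome(config)
        formats.write_gff3(genes, st.dir / "genes.gff3")
        env_sets = {}
        for env in (1, 2):
            dmrs = methylome.call_dmrs(records[records["environment"] == env])
            env_sets[env] = methylome.dmr_gene_link(dmrs, genes)
            formats.write_bed([d.interval for d in dmrs],
                              st.dir / f"dmrs_env{env}.bed",
                              names=[f"{d.context}:{d.direction}" for d in dmrs])
        shared = methylome.shared_across_environments(env_sets[1], env_sets[2])
        formats.write_tsv(
            pd.DataFrame([(d, g) for d, gs in shared.items()
                          for g in sorted(gs)],
                         columns=["direction", "gene"]),
            st.dir / "shared_gene_sets.tsv")
    report.append("## Sex-differential methylation")
    report.append(f"- male-hyper genes shared across environments: "
                  f"{sorted(shared['male-hyper'])}")
    report.append(f"- female-hyper genes shared across environments: "
                  f"{sorted(shared['female-hyper'])}")
    if compare_truth:
        target = truth_dmrs[0]
        report.append(f"- implanted male-hyper promoter recovered: "
                      f"{'ARR17_like' in shared['male-hyper']}")
    report.append("")

    # ---- expression -------------------------------------------------------
    with _Stage(manifest, "express", outdir) as st:
        counts, lengths, samples, labels = simdata.simulate_expression(config)
        formats.write_tsv(counts.reset_index(names="gene"),
                          st.dir / "counts.tsv")
        formats.write_tsv(samples, st.dir / "samples.tsv")
        fp = expression.fpkm(counts, lengths)
        flags = expression.expressed_flag(fp, samples)
        de = {}
        for t in config.expr.tissues:
            sub = samples[samples["tissue"] == t]
            grp = pd.Series(sub["sex"].to_numpy(), index=sub["sample"])
            de[t] = expression.de_test(counts[sub["sample"]], grp)
        classes = expression.classify(flags, de,
                                      tissues=tuple(config.expr.tissues))
        partition = expression.tissue_partition(classes)
        formats.write_tsv(classes.reset_index(names="gene"),
                          st.dir / "classes.tsv")
        formats.write_tsv(partition.reset_index(), st.dir / "venn.tsv")
    report.append("## Expression classes (gene counts per bucket)")
    report.append(partition.to_string())
    if compare_truth:
        agree = (classes == labels).to_numpy().mean()
        report.append(f"\n- agreement with implanted truth labels: "
                      f"{agree:.3f}")
    report.append("")

    (outdir / "manifest.json").write_text(manifest.to_json())
    (outdir / "report.md").write_text("\n".join(report) + "\n")
    return manifest
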