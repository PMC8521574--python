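"""End-to-end orchestration: simulate -> orthogroups -> signatures -> call.

Each stage writes its outputs under the configured working directory; the
final manifest records every file with a SHA-256 checksum, so byte-identical
reruns are directly checkable. Reruns with identical configuration and seeds
are deterministic.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from .alignments import ProteinAlignment, read_cds_fasta, thread_codons
from .branch_site import BranchSiteModel, selection_signature
from .config import PipelineConfig
from .divergence import divergence_record
from .msa import SignatureRecord, call_msa, records_to_frame, summarize
from .orthogroups import (
    SpeciesPanel,
    filter_all_species,
    parse_orthogroup_table,
    pick_representatives,
    select_fuzzy_one_to_one,
)
from .simulate import SimConfig, simulate_tree, write_fixture_set
from .trees import PhyloTree
from .unique_subs import (
    calls_to_frame,
    compute_gap_mask,
    find_unique_substitutions,
    unique_substitution_signature,
)

log = logging.getLogger("evosig")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _panel_from_config(config: PipelineConfig) -> SpeciesPanel:
    species = config.panel.species
    if not species:
        species = [f"sp{i + 1:02d}" for i in range(config.simulate.n_species)]
    return SpeciesPanel(
        species=tuple(sorted(species)),
        focal=config.panel.focal,
        outgroup=config.panel.outgroup,
    )


def _simulate_stage(config: PipelineConfig, fixtures: Path) -> dict:
    sc = config.simulate
    if config.resume and (fixtures / "manifest.json").exists():
        log.info("simulate: reusing existing fixtures in %s", fixtures)
        return json.loads((fixtures / "manifest.json").read_text())
    configs = []
    for i in range(sc.n_orthogroups):
        kwargs = dict(
            n_species=sc.n_species,
            n_codons=sc.n_codons,
            mean_depth=sc.mean_depth,
            focal_species=config.panel.focal,
            outgroup_species=config.panel.outgroup,
            kappa=sc.kappa,
            omega0=sc.omega0,
            p0=sc.p0,
            p1=sc.p1,
            gap_rate=sc.gap_rate,
            gap_flank_clearance=sc.gap_flank_clearance,
            seed=config.seed * 100_003 + i,
        )
        if i < sc.n_selected:
            kwargs["omega2"] = sc.omega2
        elif i < sc.n_selected + sc.n_divergent:
            kwargs["focal_rate_multiplier"] = sc.focal_rate_multiplier
        elif i < sc.n_selected + sc.n_divergent + sc.n_unique:
            kwargs["n_planted_unique_sites"] = sc.n_planted_sites
        configs.append(SimConfig(**kwargs))
    tree = simulate_tree(
        sc.n_species,
        seed=config.seed,
        mean_depth=sc.mean_depth,
        outgroup=config.panel.outgroup,
        focal=config.panel.focal,
    )
    return write_fixture_set(configs, fixtures, species_tree=tree)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages; return the output manifest."""
    workdir = Path(config.workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    fixtures = workdir / "fixtures"
    panel = _panel_from_config(config)
    manifest: dict = {"workdir": str(workdir), "files": {}}

    if "simulate" in config.stages and config.simulate.enabled:
        _simulate_stage(config, fixtures)
        for p in sorted(fixtures.iterdir()):
            manifest["files"][f"fixtures/{p.name}"] = _sha256(p)
    if not (fixtures / "orthogroups.tsv").exists():
        raise FileNotFoundError(
            "orthogroups stage: no orthogroup table found "
            f"({fixtures / 'orthogroups.tsv'}); enable the simulate stage or "
            "provide inputs"
        )

    if not {"orthogroups", "signatures", "call"} & set(config.stages):
        manifest_path = workdir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
        return manifest

    # -- orthogroups stage -------------------------------------------------
    ogs = parse_orthogroup_table(fixtures / "orthogroups.tsv", panel)
    ogs = filter_all_species(ogs, panel)
    ogs = select_fuzzy_one_to_one(
        ogs, panel, fuzziness=config.thresholds.fuzziness,
        max_copies=config.thresholds.max_copies,
    )
    log.info("orthogroups: %d after filtering", len(ogs))

    if "signatures" not in config.stages and "call" not in config.stages:
        manifest_path = workdir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
        return manifest

    # -- signatures stage --------------------------------------------------
    th = config.thresholds
    unique_frames, divergence_rows, fit_results, records = [], [], [], []
    for og in ogs:
        prot = ProteinAlignment.from_fasta(fixtures / f"{og.id}.prot.fasta")
        cds = read_cds_fasta(fixtures / f"{og.id}.cds.fasta")
        og.sequences = {t: prot.sequence(t, ungapped=True) for t in prot.taxa}
        reps = pick_representatives(og, panel)
        rows = [prot.taxa.index(reps[sp]) for sp in panel.species]
        aln = ProteinAlignment(list(panel.species), prot.matrix[rows])
        aln.mask = compute_gap_mask(aln, flank=th.flank)

        calls = find_unique_substitutions(
            aln, panel.focal, orthogroup_id=og.id, flank=th.flank,
            cutoff=th.sift_cutoff,
        )
        unique_frames.append(calls_to_frame(calls))
        unique_flag = unique_substitution_signature(calls)

        tree_path = fixtures / f"{og.id}.nwk"
        gtree = PhyloTree.from_file(tree_path, outgroup=panel.outgroup)
        drec = divergence_record(
            og.id, gtree, panel.focal, mode=th.divergence_mode,
            ratio=th.divergence_ratio, z=th.divergence_z,
        )
        divergence_rows.append(drec)

        codon_aln_genes = thread_codons(
            ProteinAlignment([reps[sp] for sp in panel.species], aln.matrix), cds
        )
        codon_aln = type(codon_aln_genes)(list(panel.species), codon_aln_genes.codons)
        model = BranchSiteModel(codon_aln, gtree, panel.focal)
        res = model.fit(starts=config.fit_starts, seed=config.seed)
        fit_results.append(res)

        records.append(
            SignatureRecord(
                orthogroup=og.id,
                gene=reps[panel.focal],
                unique_sub_impact=bool(unique_flag),
                divergent=bool(drec.flagged),
                details={
                    "n_unique_calls": len(calls),
                    "divergence_stat": round(drec.statistic, 6),
                },
            )
        )

    selected_flags = selection_signature(fit_results, fdr=th.fdr)
    for rec, res, sel in zip(records, fit_results, selected_flags):
        rec.positively_selected = bool(sel)
        rec.details["lrt_p"] = float(f"{res.pvalue:.6g}")
        rec.details["lrt_q"] = float(f"{res.qvalue:.6g}")
        rec.details["n_selected_sites"] = len(res.selected_sites)

    # write signature tables
    unique_frames = [f for f in unique_frames if not f.empty]
    uniq_df = (
        pd.concat(unique_frames, ignore_index=True)
        if unique_frames
        else calls_to_frame([])
    )
    uniq_path = workdir / "unique_substitutions.tsv"
    uniq_df.to_csv(uniq_path, sep="\t", index=False, float_format="%.6g")

    div_df = pd.DataFrame(
        [
            {
                "orthogroup": d.orthogroup,
                "focal_root_to_tip": round(d.focal_distance, 8),
                "statistic": round(d.statistic, 8),
                "flagged": d.flagged,
                "mode": d.mode,
            }
            for d in divergence_rows
        ]
    )
    div_path = workdir / "divergence.tsv"
    div_df.to_csv(div_path, sep="\t", index=False)

    sel_df = pd.DataFrame(
        [
            {
                "orthogroup": og.id,
                "lnL_null": round(r.lnl_null, 6),
                "lnL_alt": round(r.lnl_alt, 6),
                "stat": round(r.statistic, 6),
                "p": float(f"{r.pvalue:.6g}"),
                "q": float(f"{r.qvalue:.6g}"),
                "n_selected_sites": len(r.selected_sites),
                "selected_site_columns": ",".join(map(str, r.selected_sites)),
                "converged": r.converged,
            }
            for og, r in zip(ogs, fit_results)
        ]
    )
    sel_path = workdir / "selection.tsv"
    sel_df.to_csv(sel_path, sep="\t", index=False)

    for p in (uniq_path, div_path, sel_path):
        manifest["files"][p.name] = _sha256(p)

    # -- call stage --------------------------------------------------------
    if "call" in config.stages:
        called = call_msa(records)
        report_path = workdir / "report.tsv"
        records_to_frame(called).to_csv(report_path, sep="\t", index=False)
        summary_path = workdir / "summary.json"
        summary_path.write_text(
            json.dumps(summarize(called), indent=1, sort_keys=True)
        )
        manifest["files"][report_path.name] = _sha256(report_path)
        manifest["files"][summary_path.name] = _sha256(summary_path)

    manifest_path = workdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
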