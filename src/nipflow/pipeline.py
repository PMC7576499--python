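"""End-to-end orchestration: simulation -> estimation -> reports.

``run_end_to_end`` materializes a run directory::

    traces/        one CSV + JSON sidecar per simulated trace
    kinetics.json  per-strain permeabilities, activation energies, t-tests
    pore/          synthetic channel PDB, profile TSVs, hydropathy report
    conservation/  synthetic alignment FASTA, classification report
    manifest.json  stage status, seeds, input checksums, package version

No stage mutates its inputs; all randomness flows from the config seed.  A
failed stage is recorded in the manifest and its dependents are skipped.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

from . import __version__
from .config import RunConfig
from .errors import NipflowError
from .io import write_fasta_alignment, write_profile_tsv, write_report_json, write_trace_csv
from .kinetics import run_kinetics_pipeline
from .synthetic_data import (
    AlignmentSpec,
    SyntheticStructureSpec,
    default_simulation_params,
    make_alignment,
    make_channel_structure,
    simulate_arrhenius_series,
)

logger = logging.getLogger("nipflow")

__all__ = ["run_end_to_end", "simulate_cohort"]


def simulate_cohort(config: RunConfig):
    """Simulate the full water + glycerol trace cohort for every strain."""
    traces = []
    geometry = config.geometry()
    for s_idx, strain in enumerate(config.strains):
        for k_idx, solute in enumerate(("sorbitol", "glycerol")):
            if solute == "glycerol" and strain.pgly == 0:
                # still simulate: the pipeline should report no re-swelling
                pass
            params = default_simulation_params(
                pf_true=strain.pf,
                pgly_true=strain.pgly,
                ea_water=strain.ea_water,
                ea_glycerol=strain.ea_glycerol,
                shock_solute=solute,
                geometry=geometry,
                conditions=config.conditions(solute),
                noise_sd=config.noise_sd,
                mode=config.mode,
                seed=config.seed + 100_000 * s_idx + 50_000 * k_idx,
                strain=strain.name,
                t_ref=config.t_ref,
            )
            temps = list(config.temperatures)
            if config.t_ref not in temps:
                temps.append(config.t_ref)
            traces.extend(
                simulate_arrhenius_series(params, temps, config.replicates)
            )
    return traces


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_end_to_end(config: RunConfig, out_dir) -> dict:
    """Run all stages into ``out_dir``; returns the manifest dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
        "inputs": {},
    }

    def run_stage(name: str, fn, *, needs: tuple[str, ...] = ()):
        for dep in needs:
            if manifest["stages"].get(dep, {}).get("status") != "ok":
                manifest["stages"][name] = {"status": "skipped", "needs": dep}
                logger.info("stage %s skipped (needs %s)", name, dep)
                return None
        t0 = time.perf_counter()
        try:
            result = fn()
        except NipflowError as exc:
            manifest["stages"][name] = {"status": "error", "error": str(exc)}
            logger.error("stage %s failed: %s", name, exc)
            return None
        logger.info("stage %s ok (%.2f s)", name, time.perf_counter() - t0)
        manifest["stages"][name] = {"status": "ok"}
        return result

    # --- simulate ---------------------------------------------------------
    def stage_simulate():
        traces = simulate_cohort(config)
        tdir = out / "traces"
        tdir.mkdir(exist_ok=True)
        for i, trace in enumerate(traces):
            write_trace_csv(trace, tdir / f"trace_{i:04d}.csv")
        return traces

    traces = run_stage("simulate", stage_simulate)

    # --- kinetics ---------------------------------------------------------
    def stage_kinetics():
        report = run_kinetics_pipeline(
            traces, config.geometry(), reference_temperature=config.t_ref
        )
        write_report_json(report, out / "kinetics.json")
        return report

    if traces is not None:
        run_stage("kinetics", stage_kinetics, needs=("simulate",))

    # --- pore -------------------------------------------------------------
    def stage_pore():
        from .pore_structure import (
            assign_vdw_radii,
            hydropathy_ratio,
            min_constriction,
            pore_lining_residues,
            pore_profile,
            profile_delta,
            split_regions,
            write_structure,
        )

        pdir = out / "pore"
        pdir.mkdir(exist_ok=True)
        narrow = SyntheticStructureSpec(
            constriction_radius=1.4, constriction_z=24.0, seed=config.seed
        )
        wide = SyntheticStructureSpec(
            constriction_radius=1.8, constriction_z=24.0, seed=config.seed
        )
        report: dict = {}
        profiles = {}
        for label, spec in (("native", narrow), ("mutant", wide)):
            structure = make_channel_structure(spec)
            write_structure(structure, pdir / f"{label}.pdb")
            profile = pore_profile(
                structure, search="anneal", seed=config.seed, z_step=1.0
            )
            write_profile_tsv(profile, pdir / f"{label}_profile.tsv")
            profiles[label] = (structure, profile)
            zc, rc = min_constriction(profile)
            lining = pore_lining_residues(structure, profile)
            split = split_regions(profile, zc)
            ratios = {
                region: hydropathy_ratio(
                    lining, structure, region_split=split, region=region
                )
                for region in ("whole", "upper", "lower")
            }
            report[label] = {
                "constriction_z": zc,
                "constriction_radius": rc,
                "n_lining_residues": len(lining),
                "hydropathy": {
                    region: {
                        "ratio": (r.ratio if r.ratio != float("inf") else "inf"),
                        "n_hydrophobic": r.n_hydrophobic,
                        "n_hydrophilic": r.n_hydrophilic,
                    }
                    for region, r in ratios.items()
                },
            }
        delta = profile_delta(profiles["native"][1], profiles["mutant"][1])
        report["delta"] = {
            "mean": delta.mean_delta,
            "at_constriction": delta.at_constriction,
            "constriction_z": delta.constriction_z,
        }
        write_report_json(report, pdir / "pore_report.json")
        return report

    if config.pore:
        run_stage("pore", stage_pore)

    # --- conservation -----------------------------------------------------
    def stage_conservation():
        from .conservation import classify_channel_columns, pairwise_identity

        cdir = out / "conservation"
        cdir.mkdir(exist_ok=True)
        spec = AlignmentSpec(
            n_seqs=4,
            n_cols=80,
            channel_cols=tuple(range(10, 39)),  # 29 channel columns
            seed=config.seed,
        )
        alignment, truth = make_alignment(spec)
        write_fasta_alignment(alignment.sequences, cdir / "alignment.fasta")
        (cdir / "channel_columns.json").write_text(
            json.dumps(sorted(alignment.channel_columns)) + "\n"
        )
        counts = classify_channel_columns(alignment)
        names = list(alignment.sequences)
        identities = {
            f"{a}|{b}": pairwise_identity(
                alignment.sequences[a], alignment.sequences[b]
            )
            for i, a in enumerate(names)
            for b in names[i + 1:]
        }
        report = {
            "class_counts": counts.as_dict(),
            "ground_truth_counts": {
                label: sum(1 for v in truth.values() if v == label)
                for label in ("identical", "similar", "dissimilar")
            },
            "pairwise_identity_percent": identities,
        }
        write_report_json(report, cdir / "conservation_report.json")
        return report

    if config.conservation:
        run_stage("conservation", stage_conservation)

    # checksum the inputs we wrote (traces) for reproducibility bookkeeping
    tdir = out / "traces"
    if tdir.exists():
        manifest["inputs"] = {
            p.name: _sha256(p) for p in sorted(tdir.glob("trace_*.csv"))
        }
    write_report_json(manifest, out / "manifest.json")
    return manifest
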