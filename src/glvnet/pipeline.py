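"""End-to-end pipeline: simulate/load -> classify -> infer -> topology ->
stability, with a checksummed run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from glvnet import abundance, inference, stability, topology
from glvnet.abundance import AbundanceTable
from glvnet.config import PipelineConfig
from glvnet.simulate import StudyDesign, generate_interaction_matrix, generate_study

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the partial manifest."""

    def __init__(self, stage: str, cause: Exception, manifest: dict):
        self.stage = stage
        self.manifest = manifest
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _synthetic_table(config: PipelineConfig) -> AbundanceTable:
    synth = config.synthetic
    design = StudyDesign(
        n_groups=len(synth["group_labels"]),
        replicates_per_group=synth["replicates_per_group"],
        time_grid=synth["time_grid"],
        n_taxa=synth["n_taxa"],
        library_size=synth["library_size"],
        noise_sd=synth["noise_sd"],
        seed=config.seed,
    )
    params = {}
    for offset, (label, pos_frac) in enumerate(
        zip(synth["group_labels"], synth["positive_fractions"])
    ):
        params[label] = generate_interaction_matrix(
            synth["n_taxa"],
            density=synth["density"],
            strength_scale=synth["strength_scale"],
            positive_fraction=pos_frac,
            seed=config.seed + 1000 * (offset + 1),
        )
    table, _ = generate_study(design, params)
    return table


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written to disk).

    The manifest lists each artifact with its SHA-256 checksum plus the
    configuration snapshot, so identical (config, seed) runs are
    byte-verifiable.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.snapshot(), "artifacts": {}, "groups": {}}
    artifacts = manifest["artifacts"]

    def record(name: str, path: Path) -> None:
        artifacts[name] = {"path": str(path.relative_to(outdir)), "sha256": _sha256(path)}

    stage = "load"
    try:
        t0 = time.perf_counter()
        if config.synthetic is not None:
            stage = "simulate"
            table = _synthetic_table(config)
        else:
            table = AbundanceTable.read(
                config.input["shared"], config.input["metadata"]
            )
        shared = outdir / "abundance.shared.tsv"
        meta = outdir / "abundance.metadata.tsv"
        table.write(shared, meta)
        record("shared", shared)
        record("metadata", meta)
        logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

        groups = config.groups or table.groups

        stage = "classify"
        t0 = time.perf_counter()
        records = abundance.classify_membership(
            table,
            high_cutoff=config.membership["high_cutoff"],
            rare_cutoff=config.membership["rare_cutoff"],
            scope=config.membership["scope"],
        )
        mpath = outdir / "membership.csv"
        abundance.membership_frame(records).to_csv(mpath, index=False)
        record("membership", mpath)
        logger.info("stage classify done in %.2fs", time.perf_counter() - t0)

        stage = "diversity"
        t0 = time.perf_counter()
        div = abundance.diversity_frame(table)
        dpath = outdir / "diversity.csv"
        div.to_csv(dpath, index_label="sample")
        record("diversity", dpath)
        if len(groups) >= 2:
            rows = []
            g0, g1 = groups[0], groups[1]
            for index in ("np_shannon", "inv_simpson", "chao1"):
                p = abundance.permutation_t_test(
                    div.loc[div["group"] == g0, index],
                    div.loc[div["group"] == g1, index],
                    n_perm=999,
                    seed=config.seed,
                )
                rows.append({"index": index, "group_a": g0, "group_b": g1, "p_value": p})
            cpath = outdir / "diversity_comparison.csv"
            pd.DataFrame(rows).to_csv(cpath, index=False)
            record("diversity_comparison", cpath)
        logger.info("stage diversity done in %.2fs", time.perf_counter() - t0)

        fit_config = inference.FitConfig(
            regression=config.regression["backend"],
            n_components=config.regression["n_components"],
            ridge_lambda=config.regression["ridge_lambda"],
            pseudocount=config.regression["pseudocount"],
        )
        profiles = {}
        for group in groups:
            stage = f"infer[{group}]"
            t0 = time.perf_counter()
            sub_meta = table.metadata[table.metadata["group"] == group]
            n_reps = sub_meta["replicate"].nunique()
            n_days = sub_meta["day"].nunique()
            total = n_reps**n_days
            n_subsample = min(int(config.ensemble["n_subsample"]), total)
            assemblies = inference.enumerate_assemblies(
                n_reps,
                n_days,
                mode=config.ensemble["mode"],
                n_subsample=n_subsample,
                seed=config.seed,
                ceiling=config.ensemble["ceiling"],
            )
            ensemble = inference.infer_ensemble(table, group, assemblies, fit_config)
            network = inference.consensus_network(ensemble, cutoff=config.consensus_cutoff)
            epath = outdir / f"network_{group}.edges.csv"
            network.write_edgelist(epath)
            record(f"edges[{group}]", epath)
            gpath = outdir / f"network_{group}.graphml"
            network.write_graphml(gpath)
            record(f"graphml[{group}]", gpath)
            xpath = outdir / f"network_{group}.gexf"
            network.write_gexf(xpath)
            record(f"gexf[{group}]", xpath)
            logger.info(
                "stage %s done in %.2fs (%d members, %d edges)",
                stage, time.perf_counter() - t0, ensemble.n_members, network.n_edges,
            )

            stage = f"topology[{group}]"
            t0 = time.perf_counter()
            report = topology.rank_aggregate(topology.centralities(network))
            rpath = outdir / f"centrality_{group}.csv"
            report.write_csv(rpath)
            record(f"centrality[{group}]", rpath)
            for focal in config.focal_taxa:
                if focal not in network.taxa:
                    logger.warning("focal taxon %r not in %s network", focal, group)
                    continue
                ftab = topology.focal_report(network, focal)
                fpath = outdir / f"focal_{group}_{focal}.csv"
                ftab.to_frame().to_csv(fpath, index=False)
                record(f"focal[{group}][{focal}]", fpath)
            manifest["groups"][group] = {
                "n_members": ensemble.n_members,
                "n_edges": network.n_edges,
                "fragmentation": topology.fragmentation(network),
                "key_taxa": report.key_taxa,
            }
            logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

            stage = f"stability[{group}]"
            profiles[group] = stability.stability_profile(ensemble, network, group)
            ppath = outdir / f"stability_{group}.csv"
            profiles[group].to_frame().to_csv(ppath, index=False)
            record(f"stability[{group}]", ppath)

        if len(groups) >= 2:
            stage = "stability_comparison"
            comparison = stability.compare_stability(
                profiles[groups[0]], profiles[groups[1]], seed=config.seed
            )
            spath = outdir / "stability_comparison.json"
            with open(spath, "w") as fh:
                json.dump(comparison, fh, indent=2, sort_keys=True, default=float)
            record("stability_comparison", spath)
    except Exception as exc:  # noqa: BLE001 - annotate with the failing stage
        partial = outdir / "manifest.partial.json"
        with open(partial, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        raise PipelineError(stage, exc, manifest) from exc

    mpath = outdir / "manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
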