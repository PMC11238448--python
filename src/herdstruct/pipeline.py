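"""End-to-end pipeline: simulate or load, filter, relate, admix, score,
network, ROH, islands, pedigree comparison.

One TOML config drives the whole run.  A single master seed derives one
deterministic sub-seed per stage (hash-based, splitmix-style), so any stage
can be rerun in isolation and a rerun with the same config is
bit-identical.  Every stage writes TSV/GraphML/NEXUS artifacts into the
output directory, and a ``manifest.json`` records parameters, seeds, input
hashes, package version and the artifact list.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from herdstruct import __version__, admixture, contributors, islands, network
from herdstruct import genotype_io, pedigree as ped_mod, relationship, roh, sim

log = logging.getLogger("herdstruct")

STAGES = ["filter", "relationship", "admixture", "contributors", "network",
          "roh", "islands", "pedigree"]


def derive_seed(master: int, stage: str) -> int:
    """Deterministic per-stage sub-seed from the master seed."""
    h = hashlib.blake2b(f"{master}:{stage}".encode(), digest_size=4)
    return int.from_bytes(h.digest(), "big") % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(path) -> dict:
    import tomllib

    with open(path, "rb") as fh:
        return tomllib.load(fh)


def run_pipeline(config: dict, outdir) -> Path:
    """Run the configured stages; returns the output directory.

    ``config`` keys (all optional except one data source):
      ``[simulate]``        SimConfig fields, or
      ``[input]``           ped/map (or vcf) and pedigree paths;
      ``[stages]``          booleans enabling stages (default: all on);
      ``[maf]`` ``[roh]`` ``[admixture]`` ``[contributors]`` ``[network]``
      ``[islands]`` ``[pedigree]``  per-stage parameters;
      ``seed``              master seed (default 0).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = {s: True for s in STAGES}
    stages.update(config.get("stages", {}))
    manifest: dict = {
        "version": __version__, "seed": seed, "config": config,
        "stage_seeds": {s: derive_seed(seed, s) for s in STAGES},
        "artifacts": [], "input_hashes": {}, "timings_s": {},
    }

    def emit(name: str, writer) -> Path:
        path = out / name
        writer(path)
        manifest["artifacts"].append(name)
        return path

    def timed(stage):
        class _T:
            def __enter__(self):
                self.t0 = time.time()
                log.info("stage %s: start", stage)
                return self

            def __exit__(self, exc_type, exc, tb):
                manifest["timings_s"][stage] = round(time.time() - self.t0, 3)
                if exc_type is not None:
                    log.error("stage %s: FAILED (%s)", stage, exc)
                else:
                    log.info("stage %s: done in %.2fs", stage,
                             manifest["timings_s"][stage])
        return _T()

    truth = None
    pedigree = None
    home_breed = None
    if "simulate" in config:
        with timed("simulate"):
            raw = dict(config["simulate"])
            raw.setdefault("seed", derive_seed(seed, "simulate"))
            if "chromosomes" in raw:
                raw["chromosomes"] = tuple(
                    sim.Chromosome(str(c[0]), int(c[1]), float(c[2]))
                    for c in raw["chromosomes"])
            if "crossbreeding_events" in raw:
                raw["crossbreeding_events"] = tuple(
                    (int(e[0]), str(e[1]), str(e[2]), int(e[3]))
                    for e in raw["crossbreeding_events"])
            for key in ("fst_per_breed", "ancestral_freq_range"):
                if key in raw:
                    raw[key] = tuple(raw[key])
            cfg = sim.SimConfig(**raw)
            dataset, truth, pedigree = sim.simulate(cfg)
            home_breed = cfg.breed_names[0]
            emit("simulated.vcf", lambda p: genotype_io.write_vcf(dataset, p))
            emit("pedigree.tsv", lambda p: pedigree.to_tsv(p))
            emit("truth.tsv", lambda p: truth.to_tsv(p))
            l_auto_mb = sum(c.length_bp for c in cfg.chromosomes) / 1e6
    elif "input" in config:
        with timed("load"):
            inp = config["input"]
            if "vcf" in inp:
                dataset = genotype_io.read_vcf(inp["vcf"],
                                               inp.get("populations"))
                manifest["input_hashes"][inp["vcf"]] = _sha256(Path(inp["vcf"]))
            else:
                dataset = genotype_io.read_plink_text(inp["ped"], inp["map"])
                for key in ("ped", "map"):
                    manifest["input_hashes"][inp[key]] = _sha256(Path(inp[key]))
            if "pedigree" in inp:
                pedigree = ped_mod.Pedigree.from_tsv(inp["pedigree"])
                manifest["input_hashes"][inp["pedigree"]] = _sha256(
                    Path(inp["pedigree"]))
            home_breed = inp.get("home_breed")
            l_auto_mb = float(config.get("roh", {}).get("l_auto_mb",
                                                        roh.L_AUTO_MB))
    else:
        raise ValueError("config needs a [simulate] or [input] section")
    home_breed = config.get("pedigree", {}).get("home_breed", home_breed)

    if stages.get("filter", True):
        with timed("filter"):
            thr = float(config.get("maf", {}).get("threshold", 0.05))
            dataset = genotype_io.maf_filter(dataset, thr)
            log.info("MAF filter kept %d markers", dataset.n_markers)

    G = D = None
    if stages.get("relationship", True):
        with timed("relationship"):
            G = relationship.ibs_matrix(dataset)
            D = relationship.distance_matrix(G)
            emit("ibs_matrix.tsv", G.write_tsv)
            pres = relationship.pca(G)
            coords = pd.DataFrame(
                pres.coordinates(min(10, dataset.n_samples)),
                index=G.ids).add_prefix("PC")
            emit("pca_coordinates.tsv", lambda p: coords.to_csv(p, sep="\t"))
            fst = relationship.pairwise_fst(dataset)
            emit("fst_matrix.tsv",
                 lambda p: fst.to_dataframe().to_csv(p, sep="\t"))
            emit("fst_distances.nex",
                 lambda p: relationship.export_nexus_distances(fst, p))

    fit_sup = None
    if stages.get("admixture", True):
        with timed("admixture"):
            acfg = config.get("admixture", {})
            K = int(acfg.get("K", len(set(dataset.samples["population"]))))
            fit = admixture.fit_unsupervised(
                dataset, K, seed=derive_seed(seed, "admixture"),
                max_iter=int(acfg.get("max_iter", 2000)),
                n_restarts=int(acfg.get("n_restarts", 3)))
            emit("admixture_Q_unsupervised.tsv",
                 lambda p: fit.Q.to_csv(p, sep="\t"))
            refs = acfg.get("reference_populations")
            if refs is None and home_breed is not None:
                refs = [p for p in dict.fromkeys(dataset.samples["population"])]
            if refs:
                labels = {
                    s: p for s, p in zip(dataset.samples["id"],
                                         dataset.samples["population"])
                    if p in refs and not s.startswith("X")
                }
                targets = [s for s in dataset.ids if s not in labels]
                if targets:
                    fit_sup = admixture.fit_supervised(dataset, labels, targets)
                    emit("admixture_Q_supervised.tsv",
                         lambda p: fit_sup.Q.to_csv(p, sep="\t"))
                    if home_breed in fit_sup.Q.columns:
                        ag = admixture.agen(fit_sup, home_breed)
                        emit("agen.tsv",
                             lambda p: ag.rename("A_GEN").to_csv(p, sep="\t"))

    scores = None
    if stages.get("contributors", True) and G is not None:
        with timed("contributors"):
            ccfg = config.get("contributors", {})
            pa = contributors.parallel_analysis(
                G, dataset, P=float(ccfg.get("P", 0.01)),
                iterations=int(ccfg.get("iterations", 1000)),
                seed=derive_seed(seed, "contributors"),
                null=ccfg.get("null", "permute"))
            k = max(1, pa.k_significant)
            scores = contributors.contribution_scores(G, k)
            emit("contribution_scores.tsv",
                 lambda p: scores.to_frame().to_csv(p, sep="\t"))

    seg = summary = None
    if stages.get("roh", True):
        with timed("roh"):
            rcfg = {k: v for k, v in config.get("roh", {}).items()
                    if k != "l_auto_mb"}
            params = roh.ROHParams(**rcfg)
            seg = roh.detect_roh(dataset, params)
            emit("roh_segments.tsv", lambda p: seg.to_csv(p, sep="\t",
                                                          index=False))
            summary, per_pop = roh.summarize_roh(seg, dataset.samples,
                                                 l_auto_mb)
            emit("roh_summary.tsv", lambda p: summary.to_csv(p, sep="\t",
                                                             index=False))
            emit("roh_breed_summary.tsv", lambda p: per_pop.to_csv(p, sep="\t"))
            if len(seg):
                prof = roh.length_class_profile(seg, dataset.populations)
                emit("roh_length_classes.tsv",
                     lambda p: prof.to_csv(p, sep="\t"))

    if stages.get("islands", True) and seg is not None:
        with timed("islands"):
            icfg = config.get("islands", {})
            by_pop = {}
            for pop in dict.fromkeys(dataset.samples["population"]):
                inc = islands.snp_incidence(seg, dataset, pop)
                isl = islands.detect_islands(
                    inc, dataset, pop,
                    threshold=float(icfg.get("threshold", 0.5)))
                by_pop[pop] = isl
            allisl, overlaps = islands.classify_islands(
                by_pop, min_shared_snps=int(icfg.get("min_shared_snps", 2)))
            overlaps = islands.islands_with_positions(overlaps, dataset)
            emit("roh_islands.tsv", lambda p: allisl.to_csv(p, sep="\t",
                                                            index=False))
            emit("roh_island_overlaps.tsv",
                 lambda p: overlaps.to_csv(p, sep="\t", index=False))

    if stages.get("network", True) and D is not None:
        with timed("network"):
            ncfg = config.get("network", {})
            k = min(int(ncfg.get("knn", 10)), dataset.n_samples - 1)
            graph = network.knn_network(D, k=k,
                                        mutual=bool(ncfg.get("mutual", False)))
            network.annotate(
                graph, populations=dataset.populations,
                scores=scores.scores if scores is not None else None,
                roh_summary=summary,
                admixture_q=fit_sup.Q.reindex(dataset.ids).fillna(0.0)
                if fit_sup is not None else None)
            emit("network.graphml", lambda p: network.write_graphml(graph, p))
            emit("network_edges.tsv",
                 lambda p: network.write_edge_list(graph, p))

    if stages.get("pedigree", True) and pedigree is not None:
        with timed("pedigree"):
            fped = ped_mod.inbreeding(pedigree)
            emit("fped.tsv", lambda p: fped.rename("F_PED").to_csv(p, sep="\t"))
            if home_breed is not None:
                pcfg = config.get("pedigree", {})
                aped = ped_mod.pedigree_admixture(
                    pedigree, home_breed,
                    purebred_cutoff_year=int(pcfg.get("purebred_cutoff_year",
                                                      1950)))
                emit("aped.tsv",
                     lambda p: aped.rename("A_PED").to_csv(p, sep="\t"))
            if summary is not None:
                froh = summary.set_index("id")["F_ROH_pct"] / 100.0
                rep = ped_mod.compare_genomic_pedigree(froh, fped)
                emit("comparison.json", lambda p: Path(p).write_text(
                    json.dumps({"froh_vs_fped": rep.__dict__}, indent=2)))

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
    log.info("pipeline finished: %d artifacts in %s",
             len(manifest["artifacts"]), out)
    return out
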