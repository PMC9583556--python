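"""Stage orchestration over a workspace directory.

Every stage reads the plain-text artifacts of its prerequisites from the
workspace and writes its own, so stages are resumable and independently
inspectable (TSV/BED/FASTA/MEME-minimal throughout). The
:class:`Pipeline` object carries the in-memory state; the CLI wraps it one
subcommand per stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import (
    cooccurrence,
    clustering,
    crm,
    evaluation,
    intervals,
    motifs as motifs_mod,
    network as network_mod,
    nullmodel,
    peaks as peaks_mod,
)

logger = logging.getLogger(__name__)


class MissingPrerequisite(RuntimeError):
    def __init__(self, artifact: str, producer: str):
        super().__init__(
            f"missing artifact {artifact!r}: run the {producer!r} subcommand first"
        )
        self.producer = producer


@dataclass
class RunConfig:
    """Paths, thresholds (at their standard defaults) and per-stage seeds."""

    manifest: str = ""
    genome: str = ""
    chrom_sizes: str = ""
    outdir: str = "crmkit_out"
    min_enrichment: float = 20.0
    min_peaks: int = 20
    window: int = 1000
    sc_cutoff: float = 0.7
    sim_cutoff: float = 0.8
    max_gap: int = 300
    delta: float = 1.0
    p_cutoff: float = 0.05
    seed: int = 0

    def stage_seed(self, stage: str) -> int:
        # stable per-stage streams derived from the base seed
        offsets = {"motifs": 1, "cluster": 2, "calibrate": 3, "shuffle": 4,
                   "evaluate": 5, "simulate": 6}
        return (self.seed * 101 + offsets.get(stage, 0)) % (2**31 - 1)

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        return cls(**data)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            for k, v in asdict(self).items():
                if isinstance(v, str):
                    fh.write(f'{k} = "{v}"\n')
                else:
                    fh.write(f"{k} = {v}\n")


class Pipeline:
    def __init__(self, config: RunConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        config.save(self.outdir / "run_config.toml")
        self.summary: dict = {}
        self._genome = None

    # ------------------------------------------------------------- helpers

    @property
    def genome(self):
        if self._genome is None:
            from pyfaidx import Fasta

            self._genome = Fasta(self.config.genome, as_raw=True, sequence_always_upper=True)
        return self._genome

    def _artifact(self, name: str, producer: str) -> Path:
        p = self.outdir / name
        if not p.exists():
            raise MissingPrerequisite(name, producer)
        return p

    def _write_summary(self):
        with open(self.outdir / "run_summary.json", "w") as fh:
            json.dump(self.summary, fh, indent=2, sort_keys=True)

    # -------------------------------------------------------------- stages

    def ingest(self) -> pd.DataFrame:
        """Read the manifest, filter datasets, extend peaks to windows."""
        cfg = self.config
        manifest = pd.read_csv(cfg.manifest, sep="\t")
        manifest_dir = Path(cfg.manifest).parent
        chrom_sizes = peaks_mod.read_chrom_sizes(cfg.chrom_sizes)
        kept_rows, window_rows, original_rows = [], [], []
        n_dropped = 0
        for r in manifest.itertuples():
            path = Path(r.path)
            if not path.is_absolute():
                path = manifest_dir / path
            ds = peaks_mod.read_narrowpeak(
                path, dataset_id=r.dataset_id, tf=r.tf, cell_type=r.cell_type
            )
            filtered = peaks_mod.filter_dataset(
                ds, min_enrichment=cfg.min_enrichment, min_peaks=cfg.min_peaks
            )
            if filtered is None:
                n_dropped += 1
                continue
            kept_rows.append((r.dataset_id, r.tf, r.cell_type, len(filtered)))
            for p in filtered.peaks:
                half = cfg.window // 2
                ws = max(0, p.summit - half)
                we = min(chrom_sizes[p.chrom], p.summit + (cfg.window - half))
                window_rows.append((r.dataset_id, p.chrom, ws, we, p.name))
                original_rows.append((r.dataset_id, p.chrom, p.start, p.end,
                                      p.name, r.cell_type))
        windows = pd.DataFrame(
            window_rows, columns=["dataset_id", "chrom", "start", "end", "peak_id"]
        )
        windows.to_csv(self.outdir / "windows.tsv", sep="\t", index=False)
        pd.DataFrame(
            original_rows,
            columns=["dataset_id", "chrom", "start", "end", "peak_id", "cell_type"],
        ).to_csv(self.outdir / "original_peaks.tsv", sep="\t", index=False)
        pd.DataFrame(
            kept_rows, columns=["dataset_id", "tf", "cell_type", "n_peaks"]
        ).to_csv(self.outdir / "datasets_kept.tsv", sep="\t", index=False)
        self.summary["ingest"] = {
            "datasets_kept": len(kept_rows),
            "datasets_dropped": n_dropped,
            "windows": len(windows),
        }
        self._write_summary()
        return windows

    def _load_windows(self) -> pd.DataFrame:
        return pd.read_csv(self._artifact("windows.tsv", "ingest"), sep="\t",
                           dtype={"peak_id": str})

    def motifs(self) -> list[motifs_mod.Motif]:
        """Per-dataset motif discovery on the window sequences."""
        cfg = self.config
        windows = self._load_windows()
        all_motifs: list[motifs_mod.Motif] = []
        for ds_id, grp in windows.groupby("dataset_id", sort=True):
            seqs, pids, coords = [], [], []
            for r in grp.itertuples():
                seqs.append(str(self.genome[r.chrom][r.start:r.end]))
                pids.append(str(r.peak_id))
                coords.append((r.chrom, int(r.start)))
            params = motifs_mod.DiscoveryParams(min_peaks=cfg.min_peaks)
            found = motifs_mod.discover_motifs(
                seqs, pids,
                params=params,
                seed=cfg.stage_seed("motifs"),
                dataset_id=str(ds_id),
                window_coords=coords,
            )
            locator = {
                str(r.peak_id): (r.chrom, int(r.start)) for r in grp.itertuples()
            }
            found = motifs_mod.filter_by_distinct_loci(
                found, locator, min_loci=params.min_sites
            )
            all_motifs.extend(found)
        motifs_mod.write_sites_tsv(all_motifs, self.outdir / "motif_sites.tsv")
        motifs_mod.write_meme_minimal(
            {m.motif_id: m.model() for m in all_motifs},
            self.outdir / "motifs.meme",
        )
        self.summary["motifs"] = {"motifs": len(all_motifs)}
        self._write_summary()
        return all_motifs

    def _load_motifs(self) -> list[motifs_mod.Motif]:
        return motifs_mod.read_sites_tsv(self._artifact("motif_sites.tsv", "motifs"))

    def cps(self) -> list[cooccurrence.CooccurringPair]:
        """Select co-occurring motif pairs per dataset; drop CP-less datasets."""
        all_motifs = self._load_motifs()
        by_ds: dict[str, list] = {}
        for m in all_motifs:
            by_ds.setdefault(m.dataset_id, []).append(m)
        cps: list[cooccurrence.CooccurringPair] = []
        n_dropped = 0
        for ds_id in sorted(by_ds):
            found = cooccurrence.select_cps(by_ds[ds_id], cutoff=self.config.sc_cutoff)
            if not found:
                n_dropped += 1
            cps.extend(found)
        pd.DataFrame(
            [(c.dataset_id, c.motif_i, c.motif_j, c.sc) for c in cps],
            columns=["dataset_id", "motif_i", "motif_j", "sc"],
        ).to_csv(self.outdir / "cps.tsv", sep="\t", index=False)
        self.summary["cps"] = {
            "cps": len(cps),
            "datasets_dropped": n_dropped,
            "motifs_kept": len({m for c in cps for m in (c.motif_i, c.motif_j)}),
        }
        self._write_summary()
        return cps

    def cluster(self) -> list[clustering.UniqueMotif]:
        """Cluster CP motifs across datasets and derive unique motifs."""
        cfg = self.config
        cps = pd.read_csv(self._artifact("cps.tsv", "cps"), sep="\t")
        keep_ids = set(cps.motif_i) | set(cps.motif_j)
        all_motifs = {m.motif_id: m for m in self._load_motifs() if m.motif_id in keep_ids}
        models = {mid: m.model() for mid, m in all_motifs.items()}
        graph = clustering.build_motif_graph(models, edge_cutoff=cfg.sim_cutoff)
        clusters = clustering.cluster_graph(graph, seed=cfg.stage_seed("cluster"))

        windows = self._load_windows()
        locator = {
            (r.dataset_id, str(r.peak_id)): (r.chrom, int(r.start))
            for r in windows.itertuples()
        }
        ums = []
        membership_rows = []
        for i, cl in enumerate(clusters):
            um = clustering.derive_um(
                cl, all_motifs, locator, um_id=f"UM{i}", min_sites=10,
            )
            ums.append(um)
            for mid in um.member_motifs:
                membership_rows.append((um.um_id, mid, um.drop_reason or ""))
        pd.DataFrame(
            membership_rows, columns=["um_id", "motif_id", "drop_reason"]
        ).to_csv(self.outdir / "clusters.tsv", sep="\t", index=False)
        motifs_mod.write_meme_minimal(
            {u.um_id: u.model for u in ums if u.viable}, self.outdir / "ums.meme"
        )
        with open(self.outdir / "um_sites.tsv", "w") as fh:
            fh.write("um_id\tdataset_id\tpeak_id\tchrom\tstart\tend\tstrand\n")
            for u in ums:
                if not u.viable:
                    continue
                for s in u.sites:
                    fh.write(f"{u.um_id}\t{s.dataset_id}\t{s.peak_id}\t{s.chrom}\t"
                             f"{s.start}\t{s.end}\t{s.strand}\n")
        self.summary["cluster"] = {
            "clusters": len(clusters),
            "ums": sum(1 for u in ums if u.viable),
            "ums_dropped": sum(1 for u in ums if not u.viable),
        }
        self._write_summary()
        return ums

    def _load_ums(self) -> list[clustering.UniqueMotif]:
        models = motifs_mod.read_meme_minimal(self._artifact("ums.meme", "cluster"))
        sites = pd.read_csv(self._artifact("um_sites.tsv", "cluster"), sep="\t",
                            dtype={"peak_id": str})
        ums = []
        for um_id, grp in sites.groupby("um_id", sort=True):
            ums.append(clustering.UniqueMotif(
                um_id=str(um_id),
                member_motifs=[],
                model=models[str(um_id)],
                sites=[
                    clustering.GenomicMotifSite(
                        r.dataset_id, str(r.peak_id), r.chrom,
                        int(r.start), int(r.end), r.strand
                    )
                    for r in grp.itertuples()
                ],
            ))
        return ums

    def network(self) -> network_mod.InteractionNetwork:
        ums = self._load_ums()
        net = network_mod.build_network(ums)
        net.to_edge_tsv(self.outdir / "network.tsv")
        self.summary["network"] = {
            "ums": len(net.um_ids),
            "nonzero_edges": int(np.count_nonzero(np.triu(net.weights, k=1))),
        }
        self._write_summary()
        return net

    def _load_network(self) -> network_mod.InteractionNetwork:
        return network_mod.InteractionNetwork.from_edge_tsv(
            self._artifact("network.tsv", "network")
        )

    def _covered(self) -> dict[str, np.ndarray]:
        windows = self._load_windows()
        return {
            chrom: intervals.merge(grp[["start", "end"]].to_numpy())
            for chrom, grp in windows.groupby("chrom")
        }

    def predict(self) -> crm.GenomePartition:
        """Project UM sites, partition CRMCs/non-CRMCs, score, call states."""
        cfg = self.config
        net = self._load_network()
        ums = [u for u in self._load_ums() if u.um_id in set(net.um_ids)]
        sites = crm.project_sites(ums, self.genome)
        covered = self._covered()
        partition = crm.partition_crmcs(sites, covered, max_gap=cfg.max_gap)
        crm.score_partition(partition, net)
        crm.write_crmc_bed(partition.crmcs, self.outdir / "crmcs.bed")
        with open(self.outdir / "non_crmcs.bed", "w") as fh:
            for chrom in sorted(partition.non_crmcs):
                for s, e in partition.non_crmcs[chrom]:
                    fh.write(f"{chrom}\t{s}\t{e}\n")
        islands = crm.merge_islands(sites)
        with open(self.outdir / "tfbs_islands.bed", "w") as fh:
            for chrom, s, e, um_ids in islands:
                fh.write(f"{chrom}\t{s}\t{e}\t{','.join(um_ids)}\n")

        # per-cell-type functional states from original (unextended) peaks
        orig = pd.read_csv(self._artifact("original_peaks.tsv", "ingest"), sep="\t")
        for cell, grp in orig.groupby("cell_type"):
            cell_peaks = {
                chrom: intervals.merge(g[["start", "end"]].to_numpy())
                for chrom, g in grp.groupby("chrom")
            }
            with open(self.outdir / f"states_{cell}.tsv", "w") as fh:
                fh.write("crmc\tstate\n")
                for i, c in enumerate(partition.crmcs):
                    fh.write(f"CRMC{i}\t{crm.functional_state(c, cell_peaks)}\n")

        non_crmc_bp = sum(
            int(np.sum(v[:, 1] - v[:, 0])) for v in partition.non_crmcs.values()
        )
        self.summary["predict"] = {
            "crmcs": len(partition.crmcs),
            "tfbs_islands": len(islands),
            "non_crmc_bp": non_crmc_bp,
            "crmc_bp": sum(c.length for c in partition.crmcs),
        }
        self._write_summary()
        return partition

    def _load_crmcs(self) -> list[crm.CRMC]:
        path = self._artifact("crmcs.bed", "predict")
        crmcs = []
        with open(path) as fh:
            for line in fh:
                f = line.rstrip("\n").split("\t")
                c = crm.CRMC(f[0], int(f[1]), int(f[2]), sites=[],
                             s_crm=float(f[4]), n_sites_hint=int(f[6]))
                c.p_value = None if f[7] == "NA" else float(f[7])
                crmcs.append(c)
        return crmcs

    def calibrate(self) -> nullmodel.ScoreDistributions:
        """Null CRMCs, empirical p-values and the FDR table."""
        cfg = self.config
        crmcs = self._load_crmcs()
        if not crmcs:
            raise RuntimeError("no CRMCs to calibrate")
        net = self._load_network()
        models = motifs_mod.read_meme_minimal(self._artifact("ums.meme", "cluster"))
        seqs = [str(self.genome[c.chrom][c.start:c.end]) for c in crmcs]
        markov = nullmodel.fit_markov(seqs)
        null_seqs = nullmodel.sample_sequences(
            markov, [c.length for c in crmcs], seed=cfg.stage_seed("calibrate")
        )
        shuffled = network_mod.shuffle_weights(net, seed=cfg.stage_seed("shuffle"))
        site_fpr = motifs_mod.DiscoveryParams().site_fpr
        thresholds = {
            u: motifs_mod.threshold_for_fpr(m, site_fpr) for u, m in models.items()
        }
        null_scores = nullmodel.score_null_sequences(
            null_seqs, models, shuffled, max_gap=cfg.max_gap,
            thresholds=thresholds,
        )
        dist = nullmodel.ScoreDistributions(
            crmc_scores=np.array([c.s_crm for c in crmcs]),
            null_scores=null_scores,
        )
        pvals = nullmodel.empirical_pvalue(dist.crmc_scores, dist)
        for c, p in zip(crmcs, pvals):
            c.p_value = float(p)
        crm.write_crmc_bed(crmcs, self.outdir / "crmcs.bed")
        pd.DataFrame({"null_score": null_scores}).to_csv(
            self.outdir / "null_scores.tsv", sep="\t", index=False
        )
        nullmodel.estimate_fdr(dist).to_csv(
            self.outdir / "fdr_table.tsv", sep="\t", index=False
        )
        n_sig = int(np.sum(pvals <= cfg.p_cutoff))
        self.summary["calibrate"] = {
            "null_crmcs": len(null_scores),
            "significant_crmcs": n_sig,
        }
        self._write_summary()
        return dist

    def evaluate(self, reference_bed, conservation_bedgraph=None) -> dict:
        """Recall of a reference element set (and matched controls); optional
        proportion-of-neutrality comparison if a conservation track is given."""
        cfg = self.config
        crmcs = self._load_crmcs()
        sig = [c for c in crmcs
               if c.p_value is not None and c.p_value <= cfg.p_cutoff]
        predicted = evaluation.ElementSet.from_tuples(
            "predicted_crms", [(c.chrom, c.start, c.end) for c in sig]
        )
        reference = evaluation.ElementSet.from_bed("reference", reference_bed)
        rec = evaluation.recall(predicted, reference)
        chrom_sizes = peaks_mod.read_chrom_sizes(cfg.chrom_sizes)
        universe = {
            chrom: np.array([[0, size]]) for chrom, size in chrom_sizes.items()
        }
        controls = evaluation.matched_controls(
            predicted, universe, seed=cfg.stage_seed("evaluate")
        )
        ctl_rec = evaluation.recall(controls, reference)
        chance = evaluation.chance_recall_expectation(
            predicted, reference, sum(chrom_sizes.values())
        )
        result = {
            "recall": rec.sensitivity,
            "control_recall": ctl_rec.sensitivity,
            "chance_expectation": chance,
            "n_predicted": len(predicted),
            "n_reference": len(reference),
            "length_ratio": evaluation.length_ratio_stats(rec.mapping).to_dict(),
        }
        if conservation_bedgraph is not None:
            profile = evaluation.NeutralityProfile.from_bedgraph(
                conservation_bedgraph, delta=cfg.delta
            )
            crmc_iv = evaluation.ElementSet.from_tuples(
                "crmcs", [(c.chrom, c.start, c.end) for c in crmcs]
            ).intervals
            non = {}
            with open(self._artifact("non_crmcs.bed", "predict")) as fh:
                rows = [line.split("\t")[:3] for line in fh if line.strip()]
            for chrom, s, e in rows:
                non.setdefault(chrom, []).append((int(s), int(e)))
            non = {c: np.asarray(v) for c, v in non.items()}
            result["neutrality_crmc"] = evaluation.proportion_of_neutrality(
                crmc_iv, profile
            )
            result["neutrality_non_crmc"] = evaluation.proportion_of_neutrality(
                non, profile
            )
        with open(self.outdir / "evaluation.json", "w") as fh:
            json.dump(result, fh, indent=2)
        self.summary["evaluate"] = {
            k: v for k, v in result.items() if not isinstance(v, dict)
        }
        self._write_summary()
        return result

    def run_all(self, reference_bed=None, conservation_bedgraph=None) -> dict:
        self.ingest()
        self.motifs()
        self.cps()
        self.cluster()
        self.network()
        self.predict()
        self.calibrate()
        if reference_bed is not None:
            self.evaluate(reference_bed, conservation_bedgraph)
        return self.summary
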