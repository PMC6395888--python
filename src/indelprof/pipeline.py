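"""Shared configuration, stage execution, and input validation."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

from . import calling, homology, metrics, simulate
from .events import profiles_from_frame, profiles_to_frame
from .sites import read_site_table


@dataclass
class PipelineConfig:
    """Every fixed constant of the analysis, serializable to JSON."""

    window: int = 5
    min_mapq: int = 38
    min_site_reads: int = 10
    min_insertions_for_commonest: int = 5
    precision_imprecise_max: float = 0.25
    precision_middle_max: float = 0.5
    max_mh: int = 50
    treatment_min_fraction: float = 0.01
    treatment_top_n: int = 10
    n_clusters: int = 4
    # simulator
    n_sites: int = 20
    n_reads_per_site: int = 5000
    flank_len: int = 200
    # model hyperparameters
    hidden_units: int = 512
    epochs: int = 800
    learning_rate: float = 0.001
    momentum: float = 0.9
    batch_size: int = 100
    xavier_constant: float = 2.24
    lasso_alpha: float = 0.002592943797404667
    n_perm: int = 10
    n_boot: int = 20
    # seeds
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.precision_imprecise_max < self.precision_middle_max <= 1):
            raise ValueError("precision thresholds must satisfy 0 < a < b <= 1")
        if self.window < 1 or self.min_mapq < 0 or self.min_site_reads < 0:
            raise ValueError("thresholds out of range")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    @property
    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def write_manifest(stage: str, config: PipelineConfig, inputs: dict, out_dir) -> str:
    manifest = {
        "stage": stage,
        "config_hash": config.config_hash,
        "seed": config.seed,
        "inputs": {k: _checksum(v) for k, v in inputs.items()},
    }
    path = os.path.join(out_dir, f"{stage}.manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return path


def validate_inputs(paths: dict, config: PipelineConfig) -> list[str]:
    """Schema checks for SAM/FASTA/TSV inputs; returns a violation list."""
    violations: list[str] = []
    site_path = paths.get("sites")
    if site_path:
        if not os.path.exists(site_path):
            violations.append(f"missing site table: {site_path}")
        else:
            try:
                sites = read_site_table(site_path)
                if not sites:
                    violations.append("site table is empty")
            except (ValueError, KeyError) as exc:
                violations.append(f"site table invalid: {exc}")
    sam_path = paths.get("reads")
    if sam_path:
        if not os.path.exists(sam_path):
            violations.append(f"missing reads file: {sam_path}")
        else:
            try:
                simulate.read_sam_records(sam_path)
            except Exception as exc:  # pysam raises various types
                violations.append(f"reads file unreadable: {exc}")
    return violations


def run_simulate(config: PipelineConfig, out_dir) -> None:
    os.makedirs(out_dir, exist_ok=True)
    sites = simulate.make_target_sites(
        config.n_sites, seed=config.seed, flank_len=config.flank_len
    )
    bundles = []
    for i, site in enumerate(sites):
        truth = simulate.build_truth_model(site, seed=config.seed)
        bundles.append(
            simulate.simulate_reads(
                site, truth, config.n_reads_per_site, seed=config.seed + 1 + i
            )
        )
    simulate.write_fixture(bundles, out_dir)
    write_manifest("simulate", config, {}, out_dir)


def run_call_indels(config: PipelineConfig, in_dir, out_dir) -> None:
    os.makedirs(out_dir, exist_ok=True)
    sam = os.path.join(in_dir, "reads.sam")
    site_table = os.path.join(in_dir, "sites.tsv")
    for p in (sam, site_table):
        if not os.path.exists(p):
            raise FileNotFoundError(f"required input missing: {p}")
    sites = read_site_table(site_table)
    by_ref = simulate.read_sam_records(sam)
    profiles = []
    rejects: list = []
    for site in sites:
        prof = calling.call_site_profile(
            by_ref.get(site.ref_name, []),
            site,
            min_mapq=config.min_mapq,
            window=config.window,
            rejects_log=rejects,
        )
        profiles.append(prof)
    profiles = calling.filter_low_count_sites(profiles, config.min_site_reads)
    profiles_to_frame(profiles).to_csv(
        os.path.join(out_dir, "profiles.tsv"), sep="\t", index=False
    )
    with open(os.path.join(out_dir, "rejects.log"), "w") as fh:
        for read_id, reason in rejects:
            fh.write(f"{read_id}\t{reason}\n")
    write_manifest(
        "call-indels", config, {"reads": sam, "sites": site_table}, out_dir
    )


def run_profile(config: PipelineConfig, profiles_tsv, out_dir) -> None:
    import pandas as pd

    os.makedirs(out_dir, exist_ok=True)
    profiles = profiles_from_frame(pd.read_csv(profiles_tsv, sep="\t"))
    nonempty = [p for p in profiles if p.total_indel_reads > 0]
    metrics.precision_summary_table(nonempty).to_csv(
        os.path.join(out_dir, "precision_summary.tsv"), sep="\t", index=False
    )
    spectra = metrics.size_spectrum_matrix(nonempty)
    spectra.to_csv(os.path.join(out_dir, "size_spectra.tsv"), sep="\t")
    if len(spectra) >= config.n_clusters:
        labels, _ = metrics.cluster_size_spectra(spectra, k=config.n_clusters)
        pd.DataFrame(
            {"site_id": spectra.index, "cluster": labels}
        ).to_csv(os.path.join(out_dir, "clusters.tsv"), sep="\t", index=False)
    write_manifest("profile", config, {"profiles": profiles_tsv}, out_dir)


def run_homology(config: PipelineConfig, profiles_tsv, site_table, out_dir) -> None:
    import pandas as pd

    os.makedirs(out_dir, exist_ok=True)
    sites = {s.site_id: s for s in read_site_table(site_table)}
    profiles = profiles_from_frame(pd.read_csv(profiles_tsv, sep="\t"))
    nonempty = [p for p in profiles if p.total_indel_reads > 0]
    homology.homology_summary_table(
        nonempty, sites,
        min_insertions=config.min_insertions_for_commonest, max_n=config.max_mh,
    ).to_csv(os.path.join(out_dir, "homology_summary.tsv"), sep="\t", index=False)
    write_manifest(
        "homology", config, {"profiles": profiles_tsv, "sites": site_table}, out_dir
    )
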