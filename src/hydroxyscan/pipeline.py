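"""Config-driven orchestration of the full analysis.

Stages run in dependency order (digest -> quant -> annotate -> normalize ->
diff -> dhmr -> cluster), every stage writes only under the configured
output directory, and a manifest records input hashes, effective parameters
and the seed so a rerun with the same config is byte-identical for the
deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotate import GeneModels, annotate_sites, read_cgi_bed
from .cluster import select_top_sites, two_way_cluster
from .dhmr import DhmrParams, bonferroni_bins, dhmr_scan
from .diff import diff_table, summarize_direction
from .digest import SiteMap, find_ccgg_sites
from .normalize import FilterParams, filter_low_counts, log_cpm, quantile_normalize
from .quant import (
    ReadFilterParams,
    SiteCountMatrix,
    count_sites,
    filter_and_trim,
    place_reads,
    read_fastq,
)
from .samples import paired_samples, read_sample_sheet, validate_sample_sheet

log = logging.getLogger("hydroxyscan")

_KNOWN_KEYS = {
    "out_dir", "seed", "log_level", "stages",
    "inputs", "quant", "normalize", "diff", "dhmr", "cluster", "annotate",
}
_KNOWN_SUBKEYS = {
    "inputs": {"fasta", "gtf", "cgi_bed", "counts_tsv", "sample_sheet", "fastq"},
    "quant": {"p5_motif", "p7_adapter", "min_length", "quality_floor"},
    "normalize": {"min_count", "min_samples", "prior_count", "libsize_adjust", "group_by"},
    "diff": {"contrast", "paired_by", "fc_thresh", "p_thresh", "within"},
    "dhmr": {"k", "max_span", "direction", "collapse"},
    "cluster": {"p_thresh", "max_sites", "heatmap"},
    "annotate": {"promoter_span", "shore_span", "shelf_span"},
}
ALL_STAGES = ["digest", "quant", "annotate", "normalize", "diff", "dhmr", "cluster"]


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    out_dir: str = "run"
    seed: int = 0
    log_level: str = "INFO"
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    inputs: dict = field(default_factory=dict)
    quant: dict = field(default_factory=dict)
    normalize: dict = field(default_factory=dict)
    diff: dict = field(default_factory=dict)
    dhmr: dict = field(default_factory=dict)
    cluster: dict = field(default_factory=dict)
    annotate: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for section, allowed in _KNOWN_SUBKEYS.items():
            extra = set(raw.get(section, {})) - allowed
            if extra:
                raise ConfigError(f"unknown keys in [{section}]: {sorted(extra)}")
        bad = [s for s in raw.get("stages", []) if s not in ALL_STAGES]
        if bad:
            raise ConfigError(f"unknown stages: {bad}")
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def param_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _hash_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def validate_inputs(paths: dict, sample_sheet: pd.DataFrame | None = None) -> list[str]:
    """Parse-check every referenced input; return the list of failures."""
    failures: list[str] = []
    for kind, path in paths.items():
        if path is None:
            continue
        if isinstance(path, (list, tuple, dict)):
            items = path.values() if isinstance(path, dict) else path
            failures += [f"{kind}: missing file {p}" for p in items if not Path(p).exists()]
            continue
        if not Path(path).exists():
            failures.append(f"{kind}: missing file {path}")
            continue
        try:
            if kind == "fasta":
                from .digest import _as_sequences

                _as_sequences(path)
            elif kind == "gtf":
                GeneModels.from_gtf(path)
            elif kind == "cgi_bed":
                read_cgi_bed(path)
            elif kind == "counts_tsv":
                SiteCountMatrix.from_tsv(path)
            elif kind == "sample_sheet":
                sample_sheet = read_sample_sheet(path)
        except Exception as exc:  # surface every failure, do not stop early
            failures.append(f"{kind}: {exc}")
    if sample_sheet is not None:
        failures += validate_sample_sheet(sample_sheet)
    return failures


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; return the run manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "param_hash": config.param_hash(),
        "inputs": {},
        "outputs": [],
        "stats": {},
    }
    for kind, path in config.inputs.items():
        if isinstance(path, (str, Path)) and Path(path).exists():
            manifest["inputs"][kind] = {"path": str(path), "sha256": _hash_file(path)}

    failures = validate_inputs(config.inputs)
    if failures:
        raise ConfigError("input validation failed: " + "; ".join(failures))

    def emit(name: str, writer) -> Path:
        path = out_dir / name
        writer(path)
        manifest["outputs"].append(str(path))
        return path

    stages = config.stages
    sitemap = counts = sheet = None
    ann_cfg = config.annotate

    if "digest" in stages:
        log.info("digest: scanning for CCGG sites")
        sitemap = find_ccgg_sites(config.inputs["fasta"])
        manifest["stats"]["n_sites"] = len(sitemap)
        emit("sites.bed", sitemap.to_bed)
        emit("sites.tsv", sitemap.to_tsv)

    if "quant" in stages:
        if sitemap is None:
            raise ConfigError("quant requires the digest stage (missing site map)")
        fastqs = config.inputs.get("fastq")
        if fastqs:
            params = ReadFilterParams(**config.quant)
            placements = {}
            for sample, fq in fastqs.items():
                kept, report = filter_and_trim(read_fastq(fq), params)
                placements[sample] = place_reads(kept, sitemap, config.inputs["fasta"])
                manifest["stats"][f"filter_{sample}"] = report.as_dict()
            counts = count_sites(placements, sitemap)
        elif config.inputs.get("counts_tsv"):
            counts = SiteCountMatrix.from_tsv(config.inputs["counts_tsv"])
        else:
            raise ConfigError("quant stage needs fastq inputs or a counts_tsv")
        emit("counts.tsv", counts.to_tsv)

    if counts is None and config.inputs.get("counts_tsv"):
        counts = SiteCountMatrix.from_tsv(config.inputs["counts_tsv"])
    if config.inputs.get("sample_sheet"):
        sheet = read_sample_sheet(config.inputs["sample_sheet"])

    if "annotate" in stages:
        if sitemap is None:
            raise ConfigError("annotate requires the digest stage (missing site map)")
        models = GeneModels.from_gtf(config.inputs["gtf"])
        cgi = read_cgi_bed(config.inputs["cgi_bed"])
        ann = annotate_sites(sitemap, models, cgi, **ann_cfg)
        emit("annotation.tsv", lambda p: ann.rename_axis("site").to_csv(p, sep="\t"))
        manifest["stats"]["feature_fractions"] = (
            ann["feature"].value_counts(normalize=True).round(4).to_dict()
        )
        manifest["stats"]["landscape_fractions"] = (
            ann["landscape"].value_counts(normalize=True).round(4).to_dict()
        )

    norm = None
    if "normalize" in stages:
        if counts is None or sheet is None:
            raise ConfigError("normalize requires counts and a sample sheet")
        ncfg = dict(config.normalize)
        group_by = ncfg.pop("group_by", "cell_type")
        prior = ncfg.pop("prior_count", 0.5)
        adjust = ncfg.pop("libsize_adjust", 1.0)
        groups = sheet.set_index("sample")[group_by].reindex(counts.samples)
        qn = quantile_normalize(counts, groups)
        keep = filter_low_counts(qn, groups, FilterParams(**ncfg))
        manifest["stats"]["n_sites_filtered"] = int(len(keep))
        norm = log_cpm(qn.loc[keep], counts.library_sizes, prior, adjust)
        emit("normalized.tsv", lambda p: norm.rename_axis("site").to_csv(p, sep="\t"))

    dres = None
    if "diff" in stages:
        if norm is None or sheet is None:
            raise ConfigError("diff requires the normalize stage")
        dcfg = dict(config.diff)
        contrast = tuple(dcfg.get("contrast", ("NSC", "iPSC")))
        pairs = paired_samples(
            sheet, dcfg.get("paired_by", "subject"), contrast, dcfg.get("within")
        )
        dres = diff_table(
            norm,
            pairs,
            fc_thresh=dcfg.get("fc_thresh", 1.0),
            p_thresh=dcfg.get("p_thresh", 0.05),
            contrast_label=f"{contrast[0]} vs {contrast[1]}",
        )
        emit("diff.tsv", lambda p: dres.rename_axis("site").to_csv(p, sep="\t"))
        manifest["stats"]["direction"] = summarize_direction(dres)

    if "dhmr" in stages:
        if dres is None:
            raise ConfigError("dhmr requires the diff stage")
        dp = DhmrParams(**{k: v for k, v in config.dhmr.items() if k != "collapse"})
        site_tbl = pd.DataFrame(
            {
                "chrom": [s.rsplit(":", 1)[0] for s in dres.index],
                "pos": [int(s.rsplit(":", 1)[1]) for s in dres.index],
            },
            index=dres.index,
        )
        loci = dhmr_scan(dres, site_tbl, dp, collapse=config.dhmr.get("collapse", True))
        bins, thresh = bonferroni_bins(len(dres), dp.k)
        manifest["stats"]["bonferroni_bins"] = bins
        manifest["stats"]["bonferroni_threshold"] = thresh
        emit("dhmr.tsv", lambda p: loci.to_csv(p, sep="\t", index=False))
        emit(
            "dhmr.bed",
            lambda p: loci[["chrom", "start", "end"]]
            .assign(start=loci["start"] - 1)
            .to_csv(p, sep="\t", header=False, index=False),
        )

    if "cluster" in stages:
        if dres is None or norm is None:
            raise ConfigError("cluster requires the diff stage")
        ccfg = config.cluster
        top = select_top_sites(dres, ccfg.get("p_thresh", 0.01))
        max_sites = ccfg.get("max_sites", 2000)
        top = top.head(max_sites)
        manifest["stats"]["n_top_sites"] = int(len(top))
        if len(top) >= 2:
            heat = (out_dir / "heatmap.png") if ccfg.get("heatmap") else None
            cl = two_way_cluster(norm.loc[top.index], heatmap_path=heat)
            emit(
                "cluster_samples.tsv",
                lambda p: cl["sample_tree"].to_merge_table().to_csv(p, sep="\t", index=False),
            )
            emit(
                "zscores.tsv",
                lambda p: cl["z"].rename_axis("site").to_csv(p, sep="\t"),
            )
            manifest["stats"]["sample_order"] = cl["sample_order"]

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    manifest["outputs"].append(str(out_dir / "manifest.json"))
    return manifest
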