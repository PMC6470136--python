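"""End-to-end orchestration: config, manifest and the two analysis arms.

The LDSC arm runs annotation inputs -> LD scores -> stratified regression per
trait -> Bonferroni-flagged results table. The EWCE arm runs mean expression
-> specificity -> covariate-matched bootstrap per gene set -> jointly
BH-adjusted results table. Both are deterministic given the seeds in the
config, and every run writes a manifest (input digests, resolved defaults,
seed registry) before computing anything.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as sio
from .datatypes import MHC_REGION
from .ewce import EWCE
from .exceptions import ConfigurationError, DataError
from .ldsc import StratifiedLDSC, bonferroni_threshold, compute_ld_scores

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration for a pipeline run; defaults are the study constants.

    MAF filter 0.05, MHC chr6:25.5-33.5 Mb, +/-100 kb annotation windows,
    35/10 kb gene-association windows, top-10% specificity fraction and
    100,000 EWCE bootstraps are the analysis defaults; any override is logged.
    """

    out_dir: str = "results"
    inputs: dict = field(default_factory=dict)  # name -> path
    maf_min: float = 0.05
    mhc: tuple = MHC_REGION
    annotation_window: int = 100_000
    gene_window_up: int = 35_000
    gene_window_down: int = 10_000
    top_fraction: float = 0.1
    ld_window: int = 1_000_000
    n_blocks: int = 200
    weighting: str = "ldsc_weights"
    n_boot: int = 100_000
    ewce_matching: str = "length_gc_bins"
    alpha: float = 0.05
    traits: list = field(default_factory=list)  # trait -> sumstats input key
    categories: list = field(default_factory=list)
    gene_sets: dict = field(default_factory=dict)  # name -> list of genes
    seeds: dict = field(default_factory=lambda: {"ewce": 0})

    _DEFAULTS = None  # populated after class creation

    def __post_init__(self) -> None:
        self.mhc = tuple(self.mhc)
        defaults = type(self)._defaults()
        for name, default in defaults.items():
            if name in ("out_dir", "inputs", "traits", "categories",
                        "gene_sets", "seeds"):
                continue
            if getattr(self, name) != default:
                logger.info(
                    "config override: %s = %r (default %r)",
                    name, getattr(self, name), default,
                )

    @classmethod
    def _defaults(cls) -> dict:
        if cls._DEFAULTS is None:
            cls._DEFAULTS = {
                f.name: (f.default_factory() if f.default_factory
                         is not dataclasses.MISSING else f.default)
                for f in dataclasses.fields(cls)
            }
        return cls._DEFAULTS

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mhc"] = list(self.mhc)
        return d

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def validate_and_manifest(config: RunConfig) -> dict:
    """Digest all inputs and resolved defaults; refuse conflicting re-runs.

    Unreadable inputs are reported collectively. If the output directory
    already holds a manifest whose digest differs for the same manifest file
    name, the run is refused rather than silently overwriting prior results.
    """
    problems = []
    digests = {}
    for name, path in sorted(config.inputs.items()):
        p = Path(path)
        if p.is_file():
            digests[name] = _sha256(p)
            continue
        # prefix-style inputs (e.g. a panel written as <prefix>.*.tsv)
        parts = sorted(p.parent.glob(p.name + ".*")) if p.parent.is_dir() else []
        parts = [q for q in parts if q.is_file()]
        if parts:
            h = hashlib.sha256()
            for q in parts:
                h.update(q.name.encode())
                h.update(q.read_bytes())
            digests[name] = h.hexdigest()
        else:
            problems.append(f"{name}: {path} (missing or unreadable)")
    if problems:
        raise DataError("unreadable inputs:\n  " + "\n  ".join(problems))

    manifest = {
        "config": config.to_dict(),
        "input_digests": digests,
        "seeds": dict(config.seeds),
    }
    canonical = json.dumps(manifest, sort_keys=True, default=str)
    manifest["manifest_digest"] = hashlib.sha256(canonical.encode()).hexdigest()

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prior_path = out / "manifest.json"
    if prior_path.is_file():
        prior = json.loads(prior_path.read_text())
        if (
            prior.get("input_digests") == digests
            and prior.get("manifest_digest") != manifest["manifest_digest"]
        ):
            raise ConfigurationError(
                "output directory holds a differing manifest for the same "
                "inputs; refusing to overwrite (choose a new out_dir)"
            )
    prior_path.write_text(json.dumps(manifest, indent=2, sort_keys=True,
                                     default=str))
    return manifest


def run_ldsc_arm(config: RunConfig) -> pd.DataFrame:
    """LDSC arm: panel + annot + sumstats -> per trait x category results.

    Applies the MAF>5% and MHC filters, computes LD scores once, fits the
    stratified regression per trait and flags rows significant at
    ``alpha / (n_traits x n_categories)``.
    """
    manifest = validate_and_manifest(config)
    panel = sio.read_panel(config.inputs["panel_prefix"])
    annot = sio.read_annot(config.inputs["annot"], panel.variants)

    dup = [c for c in annot.categories if annot.categories.count(c) > 1]
    if dup:
        raise DataError(f"duplicated category labels: {sorted(set(dup))}")
    if config.categories:
        missing = set(config.categories) - set(annot.categories)
        if missing:
            raise DataError(f"config categories missing from annot: {missing}")
        annot = type(annot)(annot.variants,
                            annot.membership[list(config.categories)])

    keep = panel.variants.maf_mask(config.maf_min) & panel.variants.mhc_mask(
        config.mhc
    )
    panel = panel.subset(keep)
    annot = annot.subset(keep)
    ldscores = compute_ld_scores(panel, annot, window=config.ld_window)

    traits = config.traits or [
        k for k in config.inputs if k.startswith("sumstats")
    ]
    if not traits:
        raise ConfigurationError("no traits configured for the LDSC arm")
    threshold = bonferroni_threshold(
        config.alpha, len(traits), len(annot.categories)
    )

    frames = []
    for trait_key in traits:
        ss = sio.read_sumstats(config.inputs[trait_key], trait=trait_key)
        ss_keep = ss.snp.isin(set(panel.variants.snp)).to_numpy()
        ss = type(ss)(
            snp=ss.snp[ss_keep],
            chi2=ss.chi2[ss_keep],
            n_gwas=ss.n_gwas[ss_keep],
            trait=ss.trait,
        )
        model = StratifiedLDSC.from_tables(ss, ldscores)
        res = model.fit(n_blocks=config.n_blocks, weighting=config.weighting)
        frame = res.to_frame()
        part = res.partition(annot)
        frame = frame.join(part[["prop_snps", "prop_h2", "enrichment"]])
        frame.insert(0, "trait", trait_key)
        frame.insert(1, "category", frame.index)
        frame["significant"] = frame["coefficient_p"] < threshold
        frame["weighting"] = res.weighting
        frames.append(frame.reset_index(drop=True))

    results = pd.concat(frames, ignore_index=True)
    results = results.sort_values(["trait", "category"]).reset_index(drop=True)
    out = Path(config.out_dir)
    results.to_csv(out / "ldsc_results.tsv", sep="\t", index=False,
                   float_format="%.10g")
    (out / "ldsc_threshold.json").write_text(
        json.dumps(
            {
                "bonferroni_threshold": threshold,
                "n_traits": len(traits),
                "n_categories": len(annot.categories),
                "manifest_digest": manifest["manifest_digest"],
            },
            indent=2,
        )
    )
    return results


def run_ewce_arm(config: RunConfig) -> pd.DataFrame:
    """EWCE arm: expression + gene sets -> jointly BH-adjusted results grid."""
    validate_and_manifest(config)
    expr = sio.read_expression(config.inputs["expression"])
    cov = None
    if "gene_meta" in config.inputs:
        cov = sio.read_gene_meta(config.inputs["gene_meta"])
    gene_sets = dict(config.gene_sets)
    if "gene_sets_gmt" in config.inputs:
        gene_sets.update(sio.read_gmt(config.inputs["gene_sets_gmt"]))
    if not gene_sets:
        raise ConfigurationError("no gene sets configured for the EWCE arm")

    model = EWCE.from_expression(expr, cov)
    matching = config.ewce_matching if cov is not None else "none"
    result = model.test_sets(
        gene_sets,
        n_boot=config.n_boot,
        matching=matching,
        seed=int(config.seeds.get("ewce", 0)),
    )
    out = Path(config.out_dir)
    cols = ["gene_set", "cell_type", "observed", "boot_mean", "boot_sd",
            "sd_from_mean", "p", "q"]
    result.table[cols].to_csv(out / "ewce_results.tsv", sep="\t", index=False,
                              float_format="%.10g")
    return result.table
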