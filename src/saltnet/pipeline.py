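"""End-to-end orchestration: DEGs -> PIN -> SS-PIN -> co-expression -> shortlist.

``run_pipeline`` executes the full analysis from an expression matrix and a
raw interaction edge list, writing every stage's outputs under an output
directory and returning a run report of counts, cutoffs and the prioritized
genes. ``fixture_analysis`` is the fixtures-only path: it reruns the
co-expression arithmetic (connectivity, reported/unreported status,
prioritization) on a bundled or user-supplied contrast table, skipping the
expression stages.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import coexpression as cx
from . import datasets, io
from . import network as net
from . import sspin as sp
from .enrichment import hypergeom_enrich
from .errors import ConfigurationError, SaltnetError, StageError
from .expression import CASE, CONTROL, deg_table, select_degs

logger = logging.getLogger(__name__)


@dataclass
class DegParams:
    alpha: float = 0.05
    use_adjusted: bool = True
    welch: bool = False


@dataclass
class HubParams:
    multiplier: float = 2.0
    sd_mode: str = "sample"


@dataclass
class BottleneckParams:
    quantile: float = 0.25


@dataclass
class CoexprParams:
    threshold: float = 0.8
    sign: str = "positive"


@dataclass
class PrioritizeParams:
    min_connectivity: int = 3


@dataclass
class EnrichParams:
    universe: str = "network"  # or "custom"


@dataclass
class PathsConfig:
    expression: str = ""
    metadata: str = ""
    edges: str = ""
    ssg: str = ""
    annotation: str = ""   # optional: disease annotation gene list
    gmt: str = ""          # optional: enrichment library
    universe: str = ""     # optional: custom enrichment universe
    outdir: str = "saltnet_out"


@dataclass
class PipelineConfig:
    deg: DegParams = field(default_factory=DegParams)
    hub: HubParams = field(default_factory=HubParams)
    bottleneck: BottleneckParams = field(default_factory=BottleneckParams)
    coexpr: CoexprParams = field(default_factory=CoexprParams)
    prioritize: PrioritizeParams = field(default_factory=PrioritizeParams)
    enrich: EnrichParams = field(default_factory=EnrichParams)
    paths: PathsConfig = field(default_factory=PathsConfig)
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.deg.alpha <= 1:
            raise ConfigurationError(f"deg.alpha out of [0, 1]: {self.deg.alpha}")
        if not 0 < self.coexpr.threshold <= 1:
            raise ConfigurationError(
                f"coexpr.threshold out of (0, 1]: {self.coexpr.threshold}"
            )
        if not 0 <= self.bottleneck.quantile <= 1:
            raise ConfigurationError(
                f"bottleneck.quantile out of [0, 1]: {self.bottleneck.quantile}"
            )
        if self.prioritize.min_connectivity < 0:
            raise ConfigurationError("prioritize.min_connectivity must be >= 0")
        if self.hub.sd_mode not in ("sample", "population"):
            raise ConfigurationError(f"hub.sd_mode invalid: {self.hub.sd_mode!r}")
        if self.coexpr.sign not in ("positive", "absolute"):
            raise ConfigurationError(f"coexpr.sign invalid: {self.coexpr.sign!r}")
        if self.enrich.universe not in ("network", "custom"):
            raise ConfigurationError(f"enrich.universe invalid: {self.enrich.universe!r}")

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "PipelineConfig":
        if isinstance(source, (str, Path)) and "\n" not in str(source):
            raw = yaml.safe_load(Path(source).read_text())
        else:
            raw = yaml.safe_load(str(source))
        raw = raw or {}
        cfg = cls(
            deg=DegParams(**raw.get("deg", {})),
            hub=HubParams(**raw.get("hub", {})),
            bottleneck=BottleneckParams(**raw.get("bottleneck", {})),
            coexpr=CoexprParams(**raw.get("coexpr", {})),
            prioritize=PrioritizeParams(**raw.get("prioritize", {})),
            enrich=EnrichParams(**raw.get("enrich", {})),
            paths=PathsConfig(**raw.get("paths", {})),
            seed=int(raw.get("seed", 0)),
        )
        cfg.validate()
        return cfg

    def log_effective(self) -> None:
        for name, value in sorted(dataclasses.asdict(self).items()):
            logger.info("config %s = %s", name, value)


def _stage(name: str):
    """Decorator wrapping a stage so failures carry the stage name."""

    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except SaltnetError:
                raise
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise StageError(name, str(exc)) from exc

        return inner

    return wrap


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write every stage's outputs.

    Stage order: differential expression -> interaction-network cleaning and
    induction on the DEGs -> centralities -> hub/bottleneck calls -> SS-PIN
    assembly -> per-condition correlation maps -> disease thresholding and
    control contrast -> connectivity counting and prioritization ->
    (optional) enrichment. Returns the run report written to
    ``run_summary.json``.
    """
    config.validate()
    config.log_effective()
    paths = config.paths
    outdir = Path(paths.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"parameters": dataclasses.asdict(config)}

    try:
        matrix = _stage("load_expression")(io.read_expression)(
            paths.expression, paths.metadata
        )
        report["n_genes"] = len(matrix.genes)
        report["n_samples"] = len(matrix.samples)

        @_stage("differential_expression")
        def _degs():
            table = deg_table(
                matrix, config.deg.alpha, config.deg.use_adjusted, config.deg.welch
            )
            table.to_csv(outdir / "deg_table.tsv", sep="\t", float_format="%.6g")
            degs = select_degs(table, config.deg.alpha, config.deg.use_adjusted)
            io.write_gene_list(degs, outdir / "degs.txt")
            return degs

        degs = _degs()
        report["n_degs"] = len(degs)
        logger.info("differential expression: %d DEGs", len(degs))

        @_stage("interaction_network")
        def _pin():
            raw = io.read_edge_list(paths.edges)
            cleaned = net.clean_network(raw)
            pin = net.induced_subgraph(cleaned, degs)
            io.write_sif(pin, outdir / "pin.sif")
            return pin

        pin = _pin()
        report["pin_nodes"] = pin.number_of_nodes()
        report["pin_edges"] = pin.number_of_edges()
        report["pin_edge_node_ratio"] = (
            round(sp.edge_node_ratio(pin), 2) if pin.number_of_nodes() else None
        )

        @_stage("centrality")
        def _centrality():
            dc = net.degree_centrality(pin)
            bc = net.betweenness_centrality(pin)
            rows = [(g, dc[g], bc[g]) for g in sorted(dc)]
            with open(outdir / "centrality.tsv", "w") as fh:
                fh.write("gene\tdc\tbc\n")
                for g, d, b in rows:
                    fh.write(f"{g}\t{d}\t{b:.6f}\n")
            return dc, bc

        dc, bc = _centrality()

        @_stage("hubs_bottlenecks")
        def _calls():
            cutoff, hubs = net.classify_hubs(
                dc, config.hub.multiplier, config.hub.sd_mode
            )
            bottlenecks = net.classify_bottlenecks(bc, config.bottleneck.quantile)
            io.write_gene_list(hubs, outdir / "hubs.txt")
            io.write_gene_list(bottlenecks, outdir / "bottlenecks.txt")
            return cutoff, hubs, bottlenecks

        cutoff, hubs, bottlenecks = _calls()
        report["hub_cutoff"] = cutoff.cutoff
        report["n_hubs"] = len(hubs)
        report["n_bottlenecks"] = len(bottlenecks)
        logger.info(
            "hub cutoff %.3f -> %d hubs; %d bottlenecks",
            cutoff.cutoff, len(hubs), len(bottlenecks),
        )

        @_stage("sspin")
        def _sspin():
            ssgs = io.read_gene_list(paths.ssg)
            mapped = ssgs & set(pin.nodes)
            unmapped = ssgs - mapped
            if unmapped:
                logger.warning(
                    "%d SSG(s) not present in the network (kept in the label "
                    "set, excluded from the SS-PIN): %s",
                    len(unmapped), sorted(unmapped)[:10],
                )
            hbs = sp.assemble_hbs(hubs, bottlenecks, mapped, pin=pin)
            sspin_graph = sp.extract_sspin(pin, hbs.union)
            io.write_sif(sspin_graph, outdir / "sspin.sif")
            io.write_graphml(sspin_graph, outdir / "sspin.graphml")
            logger.info("HBS summary:\n%s", hbs.summary())
            return ssgs, unmapped, hbs, sspin_graph

        ssgs, unmapped, hbs, sspin_graph = _sspin()
        report["n_ssgs"] = len(ssgs)
        report["n_ssgs_unmapped"] = len(unmapped)
        report["hbs_union"] = hbs.union_size
        report["sspin_edges"] = hbs.sspin_edges

        @_stage("coexpression")
        def _coexpr():
            sspin_genes = sorted(hbs.union)
            disease_map = cx.correlation_map(matrix, CASE, sspin_genes)
            control_map = cx.correlation_map(matrix, CONTROL, sspin_genes)
            edges = cx.threshold_network(
                disease_map, config.coexpr.threshold, config.coexpr.sign
            )
            contrast = cx.contrast_conditions(edges, control_map)
            io.write_contrast(contrast, outdir / "contrast.tsv")
            return contrast

        contrast = _coexpr()
        report["n_disease_coexpression_edges"] = len(contrast)

        @_stage("prioritization")
        def _prioritize():
            incident = set(contrast["gene_1"]) | set(contrast["gene_2"])
            coexpressed_ssgs = ssgs & incident
            annotation = (
                io.read_gene_list(paths.annotation)
                if paths.annotation
                else datasets.obesity_annotation()
            )
            reported = cx.classify_reported(coexpressed_ssgs, annotation)
            counts = cx.connectivity_counts(contrast, coexpressed_ssgs)
            result = cx.prioritize(
                counts, reported, config.prioritize.min_connectivity
            )
            result.table.to_csv(outdir / "prioritization.tsv", sep="\t", index=False)
            return coexpressed_ssgs, reported, result

        coexpressed_ssgs, reported, result = _prioritize()
        report["n_coexpressed_ssgs"] = len(coexpressed_ssgs)
        report["n_unreported_ssgs"] = sum(
            1 for v in reported.values() if v == "unreported"
        )
        report["prioritized_genes"] = result.selected
        logger.info("prioritized genes: %s", ", ".join(result.selected) or "(none)")

        if paths.gmt:

            @_stage("enrichment")
            def _enrich():
                library = io.read_gmt(paths.gmt)
                if config.enrich.universe == "custom" and paths.universe:
                    universe = io.read_gene_list(paths.universe)
                else:
                    universe = set(pin.nodes)
                table = hypergeom_enrich(hbs.union & universe, library, universe)
                table.to_csv(outdir / "enrichment.tsv", sep="\t", index=False,
                             float_format="%.6g")
                return table

            enrich_table = _enrich()
            report["n_enriched_sets"] = int((enrich_table["q"] <= 0.05).sum())

        report["status"] = "ok"
    except Exception as exc:
        report["status"] = "failed"
        report["failure"] = str(exc)
        (outdir / "run_summary.json").write_text(json.dumps(report, indent=2))
        (outdir / "FAILED").write_text(str(exc) + "\n")
        raise
    (outdir / "run_summary.json").write_text(json.dumps(report, indent=2))
    return report


def fixture_analysis(
    contrast=None,
    status=None,
    annotation=None,
    min_connectivity: int = 3,
) -> dict:
    """Fixtures-only analysis: connectivity, status and shortlist from tables.

    Runs the downstream co-expression arithmetic on a contrast table
    (bundled reference table by default) and a gene/status table, skipping
    the expression and network stages. Returns connectivity counts, the
    reported/unreported classification and the prioritized shortlist.
    """
    if contrast is None:
        contrast = datasets.load_coexpression_pairs()
    if status is None:
        status = datasets.load_ssg_obesity_status()
    candidates = {str(g).upper() for g in status["gene"]}
    if annotation is None:
        annotation = datasets.obesity_annotation()
    reported = cx.classify_reported(candidates, annotation)
    counts = cx.connectivity_counts(contrast, candidates)
    unreported = {g for g, v in reported.items() if v == "unreported"}
    result = cx.prioritize(
        {g: counts[g] for g in unreported},
        {g: "unreported" for g in unreported},
        min_connectivity,
    )
    return {
        "connectivity": counts,
        "reported": reported,
        "n_unreported": len(unreported),
        "prioritized": result.selected,
        "prioritization": result,
    }
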