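"""End-to-end orchestration: mapped reactions to a rule library and metrics.

Stages: parse mapped SMILES -> (optional) ensemble consensus -> hydrogen
completion -> radius-indexed template hierarchy -> topology classification
-> DPO rule GML files -> coverage/novelty evaluation.  All randomness flows
from the single config seed; rerunning with the same config and input is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from . import chemio, clustering, dporules, hydrogen, topology
from .aam_consensus import ensemble_consensus
from .chemio import MappedReaction, parse_mapped_reaction
from .its_core import build_its, its_to_json, reaction_center

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    max_radius: int = 3
    consensus_policy: str = "strict"
    consensus_radius: int = 1
    hydrogen_cap: int = hydrogen.DEFAULT_CAP
    ambiguous_mode: str = "skip"  # skip | keep
    valence_table: dict | None = None
    seed: int = 0
    out_dir: str = "itsrules_out"

    def __post_init__(self) -> None:
        if self.max_radius < 0:
            raise ValueError("max_radius must be non-negative")
        if self.consensus_policy not in ("strict", "majority"):
            raise ValueError("consensus_policy must be 'strict' or 'majority'")
        if self.ambiguous_mode not in ("skip", "keep"):
            raise ValueError("ambiguous_mode must be 'skip' or 'keep'")
        if self.hydrogen_cap < 1:
            raise ValueError("hydrogen_cap must be at least 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def digest(self) -> str:
        """Hash of the scientific parameters (output location excluded)."""
        fields = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(fields, sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class ExtractionBundle:
    config: RunConfig
    hierarchy: clustering.TemplateHierarchy | None
    reactions: dict  # reaction id -> MappedReaction (hydrogen-complete ITS kept alongside)
    its_by_id: dict
    rule_map: dict  # (radius, reaction id) -> rule_id
    summary: dict


def _parse_input(path: str | Path) -> tuple[dict[str, list[MappedReaction]], int]:
    """Read reactions: either one mapped SMILES per line, or TSV lines
    ``reaction_id<TAB>source<TAB>mapped_smiles`` for multi-source consensus."""
    groups: dict[str, list[MappedReaction]] = {}
    failures = 0
    for i, line in enumerate(chemio.iter_reaction_lines(Path(path).read_text())):
        if "\t" in line:
            rid, _source, smi = line.split("\t")[:3]
        else:
            rid, smi = f"r{i}", line
        try:
            groups.setdefault(rid, []).append(parse_mapped_reaction(smi))
        except ValueError as exc:
            failures += 1
            logger.info("reaction %s: parse failure (%s)", rid, exc)
    return {k: v for k, v in groups.items() if v}, failures


def run_extraction(input_path: str | Path, config: RunConfig) -> ExtractionBundle:
    """Run the full extraction pipeline and write the artifact bundle.

    Writes hierarchy JSON, per-radius GML rule files, a classification TSV
    and a JSON summary (stage counts and descriptor distribution) into
    ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    groups, parse_failures = _parse_input(input_path)

    counts = {
        "parsed": len(groups),
        "parse_failures": parse_failures,
        "consensus": 0,
        "disagreement": 0,
        "hydrogen_complete": 0,
        "ambiguous_skipped": 0,
        "overflow_skipped": 0,
        "unbalanced_skipped": 0,
    }
    its_by_id: dict = {}
    rxn_by_id: dict = {}
    for rid in sorted(groups):
        sources = groups[rid]
        if len(sources) >= 2:
            res = ensemble_consensus(
                sources, policy=config.consensus_policy, r=config.consensus_radius
            )
            if res.status != "consensus":
                counts["disagreement"] += 1
                logger.info("reaction %s: consensus %s", rid, res.status)
                continue
            counts["consensus"] += 1
            its = res.representative
            rxn_by_id[rid] = sources[res.winning_sources[0]]
        else:
            counts["consensus"] += 1
            rxn = sources[0]
            its = build_its(rxn, allow_partial=not rxn.complete)
            rxn_by_id[rid] = rxn
        comp = hydrogen.enumerate_completions(its, cap=config.hydrogen_cap)
        if comp.status == "unique":
            its_by_id[rid] = comp.representative
            counts["hydrogen_complete"] += 1
        elif comp.status == "ambiguous":
            if config.ambiguous_mode == "keep":
                for k, cand in enumerate(comp.completions):
                    its_by_id[f"{rid}#alt{k}"] = cand
                    rxn_by_id[f"{rid}#alt{k}"] = rxn_by_id[rid]
                counts["hydrogen_complete"] += 1
            else:
                counts["ambiguous_skipped"] += 1
        elif comp.status == "overflow":
            counts["overflow_skipped"] += 1
        else:
            counts["unbalanced_skipped"] += 1
        if comp.status != "unique" and config.ambiguous_mode != "keep":
            rxn_by_id.pop(rid, None)

    hier = None
    rule_map: dict = {}
    cluster_sizes: list[int] = []
    descriptor_counts: dict[str, int] = {}
    type_counts: dict[str, int] = {}
    if its_by_id:
        hier = clustering.build_hierarchy(sorted(its_by_id.items()), config.max_radius)
        (out / "rules").mkdir(exist_ok=True)
        for depth, level in enumerate(hier.levels()):
            cluster_sizes.append(len(level))
            for node in sorted(level, key=lambda n: n.node_id):
                rule_id = f"r{depth}_c{node.node_id}"
                rule = dporules.template_to_rule(node.template, rule_id=rule_id)
                (out / "rules" / f"{rule_id}.gml").write_text(dporules.rule_to_gml(rule))
                for rid in node.members:
                    rule_map[(depth, rid)] = rule_id
        with (out / "hierarchy.json").open("w") as fh:
            fh.write(hierarchy_to_json(hier))
        with (out / "classification.tsv").open("w") as fh:
            fh.write("reaction_id\tdescriptor\treaction_type\ttopological_type\tstep_estimate\n")
            for rid in sorted(its_by_id):
                cls = topology.classify(reaction_center(its_by_id[rid]))
                desc = "[" + ",".join(map(str, cls.cycle_lengths)) + "]"
                descriptor_counts[desc] = descriptor_counts.get(desc, 0) + 1
                type_counts[cls.reaction_type] = type_counts.get(cls.reaction_type, 0) + 1
                fh.write(
                    f"{rid}\t{desc}\t{cls.reaction_type}\t{cls.topological_type}\t{cls.step_estimate}\n"
                )

    summary = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "stage_counts": counts,
        "clusters_per_radius": cluster_sizes,
        "descriptor_distribution": dict(sorted(descriptor_counts.items())),
        "reaction_type_distribution": dict(sorted(type_counts.items())),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    if not its_by_id:
        logger.warning("no reactions survived consensus/completion; library is empty")
    return ExtractionBundle(
        config=config,
        hierarchy=hier,
        reactions=rxn_by_id,
        its_by_id=its_by_id,
        rule_map=rule_map,
        summary=summary,
    )


def hierarchy_to_json(h: clustering.TemplateHierarchy) -> str:
    doc = {
        "max_radius": h.max_radius,
        "nodes": [
            {
                "id": n.node_id,
                "parent": n.parent,
                "depth": n.depth,
                "members": sorted(map(str, n.members)),
                "template": None
                if n.template is None
                else json.loads(
                    its_to_json(
                        n.template.graph,
                        radius=n.template.radius,
                        center_nodes=n.template.center_nodes,
                    )
                ),
            }
            for n in sorted(h.nodes.values(), key=lambda n: n.node_id)
        ],
    }
    return json.dumps(doc, indent=2, sort_keys=True) + "\n"


def run_evaluation(
    bundle: ExtractionBundle,
    reactions: dict | None = None,
    directions: tuple[str, ...] = ("forward", "backward"),
    depths: tuple[int, ...] | None = None,
) -> dict:
    """Coverage/novelty per radius and direction for Q_complete and Q_raw.

    Self-evaluation (default: the extraction set) uses each reaction's own
    rule; held-out reactions are evaluated against the whole per-radius rule
    set.  Returns a nested dict radius -> direction -> variant -> metrics.
    """
    if bundle.hierarchy is None:
        raise ValueError("bundle holds an empty library")
    if reactions is None:
        reactions = {rid: bundle.reactions[rid] for rid in bundle.its_by_id}
    held_out = any(rid not in bundle.its_by_id for rid in reactions)
    rids = sorted(reactions)
    rxns = [reactions[rid] for rid in rids]
    depths = depths if depths is not None else tuple(range(bundle.config.max_radius + 1))
    table = bundle.config.valence_table
    results: dict = {}
    for depth in depths:
        level = bundle.hierarchy.levels()[depth]
        rules = []
        raw_rules = []
        for node in sorted(level, key=lambda n: n.node_id):
            rid_ = f"r{depth}_c{node.node_id}"
            rules.append(dporules.template_to_rule(node.template, rule_id=rid_))
            try:
                raw_rules.append(
                    dporules.template_to_rule(
                        dporules.strip_hydrogens(node.template), rule_id=rid_ + "_raw"
                    )
                )
            except dporules.RuleError:
                logger.info("raw template of %s has no change left; skipped", rid_)
        rule_map = None
        if not held_out:
            rule_map = {
                i: bundle.rule_map[(depth, rid)]
                for i, rid in enumerate(rids)
                if (depth, rid) in bundle.rule_map
            }
        raw_map = (
            None
            if rule_map is None
            else {
                i: rid_ + "_raw"
                for i, rid_ in rule_map.items()
                if rid_ + "_raw" in {r.rule_id for r in raw_rules}
            }
        )
        results[depth] = {}
        for direction in directions:
            results[depth][direction] = {
                "complete": dporules.evaluate_rules(
                    rules, rxns, direction, rule_map=rule_map, valence_table=table
                ),
                "raw": dporules.evaluate_rules(
                    raw_rules, rxns, direction, rule_map=raw_map, valence_table=table
                )
                if raw_rules
                else None,
            }
    return results
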