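"""End-to-end orchestration: redundancy reduction, cross-family screen,
chain verification, superfamily assignment, trees, topology profiles and
repeat scans, with deterministic seeding and TSV/newick reporting."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .homology import (
    TransitiveChain,
    bridge_candidates,
    build_superfamilies,
    verify_chain,
)
from .pairwise import AlignmentParams, SegmentRule
from .repeats import hairpin_repeat_scan, write_repeat_report
from .seqio import (
    SequenceSet,
    read_fasta,
    reduce_redundancy,
    write_cluster_report,
    write_fasta,
)
from .topology import count_tms_by_family, predict_beta_tms, strand_count_tally
from .trees import family_tree, write_newick

log = logging.getLogger("ompbarrel")


@dataclass
class PipelineConfig:
    """All tunables with their conventional defaults.

    Defaults: BLOSUM62 with gap creation 8 / extension 2, 2000 shuffles,
    12.0 SD over >= 60 aa for homology, 85% redundancy cutoff for homology
    screens (70% for profile/tree viewing sets), 100 tree replicates.
    """

    matrix: str = "BLOSUM62"
    gap_open: int = 8
    gap_extend: int = 2
    n_shuffles: int = 2000
    sd_threshold: float = 12.0
    min_segment: int = 60
    redundancy_cutoff: float = 0.85
    tree_redundancy_cutoff: float = 0.70
    tree_replicates: int = 100
    bridge_top_k: int = 10
    min_family_members_for_tree: int = 5
    seed: int = 0

    @property
    def alignment_params(self) -> AlignmentParams:
        return AlignmentParams(
            matrix=self.matrix, gap_open=self.gap_open, gap_extend=self.gap_extend
        )

    @property
    def segment_rule(self) -> SegmentRule:
        return SegmentRule(min_length=self.min_segment, sd_threshold=self.sd_threshold)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _stage_seed(master: int, stage: str) -> int:
    return (master * 2654435761 + sum(ord(c) for c in stage)) % (2**31 - 1)


def run_pipeline(
    config: PipelineConfig,
    family_fastas: dict[str, object],
    outdir,
) -> dict:
    """Run the full analysis over named family FASTA inputs.

    ``family_fastas`` maps family label -> FASTA path or SequenceSet.
    Writes TSV/newick reports under ``outdir`` and returns a summary dict.
    Any stage failure raises with the stage name; completed outputs remain.
    """
    if len(family_fastas) < 2:
        raise ValueError("need at least 2 family inputs")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = config.alignment_params
    rule = config.segment_rule
    summary: dict = {"version": __version__, "seed": config.seed}
    config.to_file(outdir / "effective_config.yaml")

    def stage(name):
        log.info("stage: %s", name)
        summary.setdefault("stages", []).append(name)

    try:
        stage("load")
        families: dict[str, SequenceSet] = {}
        for label, src in sorted(family_fastas.items()):
            families[label] = (
                src if isinstance(src, SequenceSet) else read_fasta(src)
            )

        stage("redundancy")
        reduced: dict[str, SequenceSet] = {}
        for label, sset in families.items():
            report: list = []
            reduced[label] = reduce_redundancy(
                sset, config.redundancy_cutoff, params, report=report
            )
            write_cluster_report(report, outdir / f"clusters_{label}.tsv")

        stage("cross-family screen and chain verification")
        labels = sorted(reduced)
        family_of = {
            rec.id: label for label, sset in reduced.items() for rec in sset
        }
        chains: list[TransitiveChain] = []
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                la, lb = labels[i], labels[j]
                pairs = bridge_candidates(
                    reduced[la], reduced[lb], params, top_k=config.bridge_top_k
                )
                seed = _stage_seed(config.seed, f"chain:{la}:{lb}")
                seen_accept = False
                for k, (ra, rb) in enumerate(pairs):
                    seed_a = reduced[la][0]
                    seed_b = reduced[lb][0]
                    chain = verify_chain(
                        seed_a, ra, rb, seed_b, params, rule,
                        n_shuffles=config.n_shuffles, seed=seed + k,
                    )
                    chains.append(chain)
                    if chain.accepted:
                        seen_accept = True
                        break
                log.info("%s vs %s: %s", la, lb,
                         "linked" if seen_accept else "no accepted chain")
        write_chain_report(chains, outdir / "chains.tsv")

        stage("superfamily assignment")
        assignment = build_superfamilies(
            [c for c in chains if c.accepted], family_of
        )
        with open(outdir / "superfamilies.tsv", "w") as fh:
            fh.write("family\tcomponent\tn_supporting_chains\tstatus\n")
            for fam in sorted(assignment.component_of):
                n_sup = sum(
                    n for pair, n in assignment.support.items() if fam in pair
                )
                fh.write(
                    f"{fam}\t{assignment.component_of[fam]}\t{n_sup}\t"
                    f"{assignment.status(fam)}\n"
                )
        summary["superfamilies"] = {
            label: members for label, members in assignment.members.items()
        }

        stage("trees")
        tree_sets = {
            label: reduce_redundancy(sset, config.tree_redundancy_cutoff, params)
            for label, sset in families.items()
        }
        if len(tree_sets) >= 3:
            ftree = family_tree(
                tree_sets, params,
                min_members=config.min_family_members_for_tree,
                n_replicates=config.tree_replicates,
                seed=_stage_seed(config.seed, "family-tree"),
            )
            write_newick(ftree, outdir / "family_tree.nwk")

        stage("topology")
        counts = count_tms_by_family(tree_sets)
        with open(outdir / "strand_counts.tsv", "w") as fh:
            fh.write("family\tmodal_strands\thistogram\n")
            for fam in sorted(counts):
                fh.write(
                    f"{fam}\t{counts[fam]['modal']}\t"
                    f"{json.dumps(counts[fam]['histogram'])}\n"
                )
        summary["strand_tally"] = strand_count_tally(counts)

        stage("repeats")
        for label, sset in reduced.items():
            rec = sset[0]
            topo = predict_beta_tms(rec.ungapped)
            hits = hairpin_repeat_scan(
                rec.ungapped, topo,
                n_shuffles=config.n_shuffles,
                seed=_stage_seed(config.seed, f"repeats:{label}"),
            )
            write_repeat_report(hits, outdir / f"repeats_{label}.tsv", rec.id)

        summary["ok"] = True
        with open(outdir / "run_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=str)
        return summary
    except Exception as exc:
        failed = summary.get("stages", ["init"])[-1]
        raise RuntimeError(f"pipeline failed at stage {failed!r}: {exc}") from exc


def write_chain_report(chains: list[TransitiveChain], path) -> None:
    """TSV chain report with the four proteins and four comparison scores."""

    def fmt(z):
        return f"{z:.1f}" if z is not None else ""

    with open(path, "w") as fh:
        fh.write(
            "protein1_A\tprotein2_B\tprotein3_C\tprotein4_D\t"
            "A_vs_B\tB_vs_C\tC_vs_D\tA_vs_D\taccepted\tmethod\treason\n"
        )
        for c in chains:
            fh.write(
                f"{c.a}\t{c.b}\t{c.c}\t{c.d}\t{fmt(c.z_ab)}\t{fmt(c.z_bc)}\t"
                f"{fmt(c.z_cd)}\t{fmt(c.z_ad_direct)}\t"
                f"{int(c.accepted)}\t{c.method}\t{c.reason}\n"
            )
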