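"""End-to-end pipeline: reconstruct -> mutations -> motifs -> optional stages.

A :class:`PipelineConfig` (usually loaded from YAML) names the inputs
(alignment, tree, ingroup, core interval, motifs, enzymes, measurement
tables) and :func:`run_pipeline` executes the stages in order, writing a
deterministic report bundle: consensus FASTA (gapped and ungapped),
ambiguity TSV, mutation catalogue TSV, site/diff TSVs and BED files, and a
summary JSON carrying the seed, a config hash and row totals.  Any stage
failure raises :class:`StageError` tagged with the stage name, which the CLI
converts to a stage-specific exit code.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .activity import ActivityMeasurements, normalize_activity
from .motifs import DEFAULT_MOTIFS, Motif, diff_sites, scan_motif, sites_to_bed
from .mutations import CoreAnnotation, catalogue_for_alignment
from .parsimony import Phylogeny, fitch_reconstruct
from .rflp import BSTXI, RestrictionEnzyme, rflp_discover, segregation_test
from .seq_io import read_alignment, write_bed, write_fasta

STAGES = (
    "config", "reconstruct", "mutations", "motifs", "rflp", "segtest", "activity",
)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for exit-code tagging."""

    def __init__(self, stage: str, message: str):
        super().__init__(message)
        self.stage = stage


@dataclass
class PipelineConfig:
    """Paths and parameters for one pipeline run.

    ``core`` is a half-open alignment-column interval; ``motifs`` maps names
    to IUPAC consensi; ``enzymes`` entries are (name, recognition, cut
    offset) mappings.  ``segregation``, ``rflp`` and ``measurements`` enable
    their optional stages when present.
    """

    alignment: str
    tree: str
    ingroup: list[str]
    out_dir: str = "concestor_out"
    seed: int = 0
    core: tuple[int, int] | None = None
    motifs: dict[str, str] = field(
        default_factory=lambda: {m.name: m.consensus for m in DEFAULT_MOTIFS}
    )
    enzymes: list[dict[str, Any]] = field(
        default_factory=lambda: [
            {"name": BSTXI.name, "recognition": BSTXI.recognition,
             "cut_offset_top": BSTXI.cut_offset_top}
        ]
    )
    segregation: dict[str, list[int]] | None = None
    rflp: dict[str, Any] | None = None
    measurements: str | None = None
    reference_construct: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise StageError("config", f"{path}: config must be a mapping")
        try:
            cfg = cls(**raw)
        except TypeError as exc:
            raise StageError("config", f"{path}: {exc}") from exc
        if cfg.core is not None:
            cfg.core = (int(cfg.core[0]), int(cfg.core[1]))
        return cfg

    def motif_objects(self) -> list[Motif]:
        return [Motif(name, consensus) for name, consensus in self.motifs.items()]

    def enzyme_objects(self) -> list[RestrictionEnzyme]:
        return [
            RestrictionEnzyme(e["name"], e["recognition"], int(e["cut_offset_top"]))
            for e in self.enzymes
        ]

    def digest_hash(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, sep="\t", index=False)
    return len(df)


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute all configured stages; returns the summary dict (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.digest_hash(),
        "totals": {},
    }

    # -- reconstruct --------------------------------------------------------
    try:
        aln = read_alignment(config.alignment)
        tree = Phylogeny.from_file(config.tree, set(config.ingroup))
        recon = fitch_reconstruct(aln, tree)
    except Exception as exc:
        raise StageError("reconstruct", str(exc)) from exc
    consensus = recon.consensus_record("Concestor")
    write_fasta([consensus], out / "concestor.fasta")
    (out / "concestor_gapped.fasta").write_text(
        f">Concestor\n{recon.consensus}\n"
    )
    n_amb = _write_tsv(recon.ambiguity_table(), out / "ambiguity.tsv")
    summary["totals"]["ambiguous_sites"] = n_amb
    summary["totals"]["polymorphic_sites"] = len(recon.polymorphic_cols)
    summary["totals"]["unambiguous_polymorphic_sites"] = len(
        set(recon.polymorphic_cols) - set(recon.ambiguous_cols)
    )

    # -- mutations ----------------------------------------------------------
    try:
        core = CoreAnnotation(*config.core) if config.core else None
        catalogue = catalogue_for_alignment(
            aln, recon.consensus, config.ingroup, core
        )
    except Exception as exc:
        raise StageError("mutations", str(exc)) from exc
    summary["totals"]["mutation_events"] = _write_tsv(
        catalogue, out / "mutation_catalogue.tsv"
    )

    # -- motifs -------------------------------------------------------------
    try:
        motif_objs = config.motif_objects()
        anc_sites = [
            s for m in motif_objs for s in scan_motif(consensus, m, strands="both")
        ]
        write_bed(sites_to_bed(anc_sites), out / "concestor_sites.bed")
        site_rows = pd.DataFrame(
            [
                {
                    "seq_id": s.seq_id, "start": s.start, "end": s.end,
                    "strand": s.strand, "matched": s.matched, "motif": s.motif_name,
                }
                for s in anc_sites
            ],
            columns=["seq_id", "start", "end", "strand", "matched", "motif"],
        )
        _write_tsv(site_rows, out / "concestor_sites.tsv")
        diff_rows = []
        for allele_id in config.ingroup:
            for d in diff_sites(recon.consensus, aln, allele_id, motif_objs):
                diff_rows.append(
                    {
                        "allele_id": d.allele_id, "motif": d.site.motif_name,
                        "start": d.site.start, "end": d.site.end,
                        "strand": d.site.strand, "status": d.status,
                    }
                )
        diffs = pd.DataFrame(
            diff_rows,
            columns=["allele_id", "motif", "start", "end", "strand", "status"],
        )
    except Exception as exc:
        raise StageError("motifs", str(exc)) from exc
    summary["totals"]["ancestor_sites"] = len(site_rows)
    summary["totals"]["site_diffs"] = _write_tsv(diffs, out / "site_diffs.tsv")

    # -- optional: rflp -----------------------------------------------------
    if config.rflp is not None:
        try:
            spec = config.rflp
            a = aln.ungapped(spec["allele_a"])
            b = aln.ungapped(spec["allele_b"])
            interval = tuple(spec["amplicon"]) if "amplicon" in spec else None
            markers = rflp_discover(a, b, config.enzyme_objects(), interval)
            marker_rows = pd.DataFrame(
                [
                    {
                        "enzyme": m.enzyme.name, "allele_a": m.allele_a,
                        "allele_b": m.allele_b,
                        "pattern_a": ",".join(map(str, m.pattern_a)),
                        "pattern_b": ",".join(map(str, m.pattern_b)),
                    }
                    for m in markers
                ],
                columns=["enzyme", "allele_a", "allele_b", "pattern_a", "pattern_b"],
            )
        except Exception as exc:
            raise StageError("rflp", str(exc)) from exc
        summary["totals"]["rflp_markers"] = _write_tsv(marker_rows, out / "rflp_markers.tsv")

    # -- optional: segregation test ----------------------------------------
    if config.segregation is not None:
        try:
            res = segregation_test(
                config.segregation["counts"], config.segregation["ratio"]
            )
        except Exception as exc:
            raise StageError("segtest", str(exc)) from exc
        summary["segregation"] = {
            "observed": list(res.observed),
            "ratio": list(res.expected_ratio),
            "chi_square": res.chi_square,
            "df": res.df,
            "p_value": res.p_value,
        }

    # -- optional: activity -------------------------------------------------
    if config.measurements is not None:
        try:
            table = pd.read_csv(config.measurements, sep="\t")
            groups = {
                cid: ActivityMeasurements(
                    cid,
                    tuple(sub["intensity"]),
                    segment=str(sub["segment"].iloc[0]),
                    sex=str(sub["sex"].iloc[0]),
                )
                for cid, sub in table.groupby("construct_id", sort=True)
            }
            ref_id = config.reference_construct or sorted(groups)[0]
            ref = groups[ref_id]
            act_rows = pd.DataFrame(
                [
                    {
                        "construct_id": cid,
                        "percent": round(norm.percent, 4),
                        "sem_percent": round(norm.sem_percent, 4),
                        "n": norm.n,
                    }
                    for cid, meas in sorted(groups.items())
                    for norm in [normalize_activity(meas, ref)]
                ],
                columns=["construct_id", "percent", "sem_percent", "n"],
            )
        except Exception as exc:
            raise StageError("activity", str(exc)) from exc
        summary["totals"]["activities"] = _write_tsv(act_rows, out / "activity.tsv")

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary
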