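"""End-to-end orchestration: alignment -> tree -> selection -> dating.

``run_all`` executes the full analysis on either user-supplied files or a
simulated study bundle, writing model-ladder tables, the MK table, Tajima's D
per haplogroup, a dated tree, and a JSON manifest (versions, seeds,
wall-clock). Report tables mirror the published table layouts so comparison
is a diff, not a transformation.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import alignio, chronos, codonml, neutrality, phylo, simgen
from ._version import __version__
from .errors import UsageError

log = logging.getLogger("caprachron")


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    outdir: str
    seed: int = 1
    # either a simulate block ...
    simulate: dict | None = None
    # ... or input paths
    alignment: str | None = None
    regions: str | None = None
    haplogroups: dict[str, str] | None = None
    dloop: str | None = None
    # analysis settings
    gamma_shape_dloop: float = 0.22
    calibration_age: float = 3.4e6
    ladders: tuple[str, ...] = ("shallow", "deep")
    fit_opts: dict = field(default_factory=dict)
    clock_maxiter: int = 300

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(open(path))
        return cls.validate(raw)

    @classmethod
    def validate(cls, raw: dict) -> "RunConfig":
        if "outdir" not in raw:
            raise UsageError("config missing required key 'outdir'")
        if raw.get("simulate") is None and raw.get("alignment") is None:
            raise UsageError("config needs either a 'simulate' block or 'alignment'")
        if raw.get("calibration_age") is not None and raw["calibration_age"] <= 0:
            raise UsageError("calibration_age must be positive")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise UsageError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.ladders = tuple(cfg.ladders)
        for lad in cfg.ladders:
            if lad not in ("shallow", "deep"):
                raise UsageError(f"unknown ladder {lad!r}")
        return cfg


def _stage(name):
    log.info("stage: %s", name)


def run_all(cfg: RunConfig) -> dict:
    """Execute every stage; returns a manifest dict (also written to disk)."""
    t_start = time.time()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config": {
            "calibration_age": cfg.calibration_age,
            "gamma_shape_dloop": cfg.gamma_shape_dloop,
            "ladders": list(cfg.ladders),
        },
        "stages": [],
        "outputs": {},
    }

    def done(stage, **outputs):
        manifest["stages"].append(stage)
        for k, v in outputs.items():
            manifest["outputs"][k] = str(v)

    # ---------------------------------------------------------- inputs
    _stage("inputs")
    if cfg.simulate is not None:
        sim_kwargs = dict(cfg.simulate)
        fixture = simgen.make_study_fixture(seed=cfg.seed, **sim_kwargs)
        caln_all = fixture.codon_aln
        assignment = fixture.assignment
        dloop = fixture.dloop_aln
        fixture.write(outdir / "fixture")
        done("simulate", fixture=outdir / "fixture")
    else:
        aln = alignio.read_fasta(cfg.alignment)
        regions = alignio.read_regions(cfg.regions)
        caln_all = alignio.build_codon_alignment(aln, regions)
        if not cfg.haplogroups:
            raise UsageError("file-based runs require a 'haplogroups' mapping")
        assignment = phylo.HaplogroupAssignment(dict(cfg.haplogroups))
        caln_all.meta = dict(assignment.labels)
        dloop = alignio.read_fasta(cfg.dloop) if cfg.dloop else None
        done("inputs")

    smaller, larger = alignio.split_small_large(caln_all)
    log.info("smaller data set: %d seqs x %d codons", smaller.n, smaller.n_codons)

    # ------------------------------------------------------------ tree
    _stage("tree")
    work = smaller
    labels = {i: assignment.labels[i] for i in work.ids}
    nuc = work.to_nuc_alignment()
    dm = phylo.k80_gamma_distance(nuc, shape=1.0)
    nj = phylo.nj_tree(dm)
    cat = phylo.categorize_branches(nj, phylo.HaplogroupAssignment(labels))
    cat.to_frame().to_csv(outdir / "branch_categories.tsv", sep="\t", index=False)
    (outdir / "nj_tree.nwk").write_text(cat.tree.to_newick())
    done("tree", nj_tree=outdir / "nj_tree.nwk",
         branch_categories=outdir / "branch_categories.tsv")

    # ------------------------------------------------- selection ladders
    results3w = None
    for ladder in cfg.ladders:
        _stage(f"codonml {ladder} ladder")
        df = codonml.run_model_ladder(
            work, cat.tree, cat, f"{ladder}-family", opts=dict(cfg.fit_opts)
        )
        fname = (
            "table2_shallow_ladder.tsv" if ladder == "shallow" else "table4_deep_ladder.tsv"
        )
        df.to_csv(outdir / fname, sep="\t", index=False)
        if "3w" in df.attrs["results"]:
            results3w = df.attrs["results"]["3w"]
        done(f"ladder_{ladder}", **{fname.split(".")[0]: outdir / fname})

    # --------------------------------------------------------- neutrality
    _stage("neutrality")
    groups = sorted({v for v in labels.values() if v != "outgroup"})
    by_group = {
        g: larger.subset([i for i in larger.ids if assignment.labels.get(i) == g])
        for g in groups
    }
    mk_rows = []
    for ga, gb in combinations(groups, 2):
        a, b = by_group[ga], by_group[gb]
        if max(a.n, b.n) < 2:
            continue
        tab = neutrality.mk_contingency(a, b)
        res = neutrality.mk_statistics(tab)
        mk_rows.append(
            {
                "pair": f"{ga} vs {gb}",
                "codons_analyzed": tab.codons_analyzed,
                "Ds": tab.Ds, "Ps": tab.Ps, "Dn": tab.Dn, "Pn": tab.Pn,
                "NI": res.NI, "alpha": res.alpha, "fisher_p": res.fisher_p,
                "G": res.G, "G_williams": res.G_williams, "G_yates": res.G_yates,
            }
        )
    mk_df = pd.DataFrame(mk_rows)
    mk_df.to_csv(outdir / "table3_mk.tsv", sep="\t", index=False)

    taj_rows = []
    for g in groups:
        sub = by_group[g]
        if sub.n < 4:
            continue
        res = neutrality.tajimas_d(sub.to_nuc_alignment())
        taj_rows.append({"haplogroup": g, "n": res.n, "S": res.S,
                         "pi": res.pi, "D": res.D})
    pd.DataFrame(taj_rows).to_csv(outdir / "tajima_d.tsv", sep="\t", index=False)
    done("neutrality", table3_mk=outdir / "table3_mk.tsv",
         tajima_d=outdir / "tajima_d.tsv")

    # ------------------------------------------------------------- dating
    _stage("dating")
    third = alignio.codon_position_view(work, 3)
    ct = chronos.clock_test(third, cat.tree, maxiter=cfg.clock_maxiter)
    chron = chronos.date_tree(
        third, cat.tree, (work.ids, cfg.calibration_age), maxiter=cfg.clock_maxiter
    )
    (outdir / "chronogram.nwk").write_text(chron.tree.to_newick())
    chron.node_table().to_csv(outdir / "node_ages.tsv", sep="\t", index=False)
    manifest["clock_test"] = {
        "lnL_clock": ct.lnL_clock, "lnL_free": ct.lnL_free,
        "df": ct.df, "p": ct.p,
    }
    manifest["rate_per_site_per_year"] = chron.rate
    done("dating", chronogram=outdir / "chronogram.nwk",
         node_ages=outdir / "node_ages.tsv")

    if results3w is not None:
        manifest["omega_3w"] = results3w.omegas
    manifest["wall_clock_s"] = time.time() - t_start
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
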