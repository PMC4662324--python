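"""End-to-end orchestration: indices -> models -> ASR -> signal -> contrasts.

``run_pipeline`` sequences the full analysis from input files (or an
in-memory synthetic study) to a report bundle of CSV/JSON outputs plus a
deterministic run manifest. Every stage is a pure function of its inputs,
the configuration, and the seed, so a rerun with the same configuration
reproduces the bundle bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .asr import estimate_at_clade, inverse_logit, reml_asr, summarize_consensus_node
from .contrasts import contrast_correlation, nonphylo_correlation, standardize_branches
from .diet import compile_species_table, logit_with_boundary, read_entries
from .errors import PhyloDietError, ValidationError
from .models import MODELS, fit_model, select_models
from .signal import blomberg_k, lambda_signal
from .trees import Phylogeny, read_newick_list, strict_consensus

log = logging.getLogger("phylodiet")

__all__ = ["PipelineConfig", "run_pipeline", "write_study", "auto_consensus_nodes"]


@dataclass
class PipelineConfig:
    diet_table: str
    mass_table: str
    trees_file: str
    out_dir: str
    clades_file: Optional[str] = None  # JSON: label -> list of tip names
    trait: str = "herbivory"  # or "folivory"
    models: Sequence[str] = MODELS
    alpha: float = 0.05
    n_perm: int = 1000
    seed: int = 0
    exclude: Sequence[str] = ()

    def validate(self) -> None:
        for p in (self.diet_table, self.mass_table, self.trees_file):
            if not Path(p).exists():
                raise ValidationError(f"input file not found: {p}")
        if self.clades_file and not Path(self.clades_file).exists():
            raise ValidationError(f"input file not found: {self.clades_file}")
        if self.trait not in ("herbivory", "folivory"):
            raise ValidationError("trait must be 'herbivory' or 'folivory'")


def auto_consensus_nodes(consensus: Phylogeny, n_nodes: int = 5) -> Dict[str, frozenset]:
    """Nested chain of consensus clades: the largest non-root clade, then
    repeatedly the largest child clade; labelled A, B, C, ..."""
    dt = consensus.dendropy_tree
    root = dt.seed_node
    kids = [c for c in root.child_nodes() if not c.is_leaf()]
    if not kids:
        raise ValidationError("consensus tree has no internal structure to label")
    nd = max(kids, key=lambda c: len(c.leaf_nodes()))
    chain = {}
    labels = "ABCDEFGHIJ"
    for i in range(n_nodes):
        chain[labels[i]] = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        kids = [c for c in nd.child_nodes() if not c.is_leaf()]
        if not kids:
            break
        nd = max(kids, key=lambda c: len(c.leaf_nodes()))
    return chain


def _stage(name):
    def deco(fn):
        def wrapper(*a, **kw):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                out = fn(*a, **kw)
            except Exception as exc:
                raise PhyloDietError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done in %.1fs", name, time.perf_counter() - t0)
            return out
        wrapper.__name__ = fn.__name__
        return wrapper
    return deco


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable) + "\n")


def _jsonable(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, frozenset):
        return sorted(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


@_stage("compile-diet")
def _compile_stage(cfg: PipelineConfig, out: Path):
    entries = read_entries(cfg.diet_table)
    masses_df = pd.read_csv(cfg.mass_table)
    masses = dict(zip(masses_df["species"], masses_df["body_mass_g"]))
    table = compile_species_table(entries, masses=masses)
    table.to_csv(out / "species_table.csv", index=False)
    col = "herbivory_index" if cfg.trait == "herbivory" else "folivory_index"
    index = dict(zip(table["species"], table[col]))
    diet_tv = logit_with_boundary(index, trait_name=f"logit_{cfg.trait}")
    mass_tv = {
        s: float(np.log10(m)) for s, m in masses.items() if s in index and m > 0
    }
    _write_json(out / "transform_record.json", diet_tv.transform_record)
    return table, diet_tv, mass_tv


@_stage("load-trees")
def _trees_stage(cfg: PipelineConfig, species: Sequence[str]):
    trees = read_newick_list(cfg.trees_file)
    shared = [s for s in species if all(s in set(t.tip_labels) for t in trees)]
    if len(shared) < 4:
        raise ValidationError("fewer than 4 species shared between tables and trees")
    pruned = [
        t.prune_to(shared) if set(t.tip_labels) != set(shared) else t for t in trees
    ]
    return pruned, shared


@_stage("fit-models")
def _models_stage(cfg: PipelineConfig, trees, diet_tv, out: Path):
    sel = select_models(trees, dict(diet_tv.items()), models=cfg.models)
    sel.table.to_csv(out / "model_selection.csv", index=False)
    summary = {
        "best_model_proportions": sel.proportions,
        "aicc_mean": sel.aicc_mean,
        "aicc_sd": sel.aicc_sd,
        "n_excluded_fits": sel.n_excluded,
    }
    _write_json(out / "model_selection_summary.json", summary)
    return sel


@_stage("asr")
def _asr_stage(cfg: PipelineConfig, trees, diet_tv, sel, clades, out: Path):
    lam_by_tree = {
        int(ti): float(row["param"])
        for ti, row in sel.table[sel.table.model == "lambda"].set_index("tree_index").iterrows()
    }
    rows = []
    per_node: Dict[str, list] = {lab: [] for lab in clades}
    trait = dict(diet_tv.items())
    for ti, tree in enumerate(trees):
        lam = lam_by_tree.get(ti, 1.0)
        ests = reml_asr(trait, tree, lam)
        for lab, clade in clades.items():
            e = estimate_at_clade(ests, clade)
            if e is None:
                raise ValidationError(
                    f"consensus clade {lab} missing from tree {ti}; not a strict "
                    "consensus clade of this sample"
                )
            per_node[lab].append(e)
            lo, hi = e.ci
            bt, (blo, bhi) = e.back_transformed()
            rows.append(
                {
                    "tree_index": ti, "node": lab, "lambda": lam,
                    "estimate_logit": e.estimate, "se": e.se,
                    "ci_low_logit": lo, "ci_high_logit": hi,
                    "estimate_prop": bt, "ci_low_prop": blo, "ci_high_prop": bhi,
                }
            )
    pd.DataFrame(rows).to_csv(out / "asr_nodes.csv", index=False)
    summaries = {}
    for lab, ests in per_node.items():
        s = summarize_consensus_node(ests, label=lab)
        emin, emax = s.minmax
        summaries[lab] = {
            "n_trees": len(s.estimates),
            "mode_logit": s.mode,
            "mode_prop": float(inverse_logit(s.mode)),
            "estimate_range_logit": [emin, emax],
            "estimate_range_prop": [float(inverse_logit(emin)), float(inverse_logit(emax))],
            "ci_low_min_prop": float(inverse_logit(s.ci_low.min())),
            "ci_high_max_prop": float(inverse_logit(s.ci_high.max())),
        }
    _write_json(out / "asr_summary.json", summaries)
    return summaries


@_stage("signal")
def _signal_stage(cfg: PipelineConfig, trees, diet_tv, mass_tv, out: Path):
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for ti, tree in enumerate(trees):
        for name, tv in (("diet", dict(diet_tv.items())), ("mass", mass_tv)):
            seed_i = int(rng.integers(0, 2**31 - 1))
            k = blomberg_k(tv, tree, n_perm=cfg.n_perm, seed=seed_i)
            lam = lambda_signal(tv, tree)
            rows.append(
                {
                    "tree_index": ti, "trait": name,
                    "K": k.estimate, "K_p": k.p_value,
                    "lambda": lam.estimate, "lambda_p": lam.p_value,
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(out / "signal.csv", index=False)
    summary = {}
    for name, sub in df.groupby("trait"):
        summary[name] = {
            "K_range": [float(sub.K.min()), float(sub.K.max())],
            "K_p_max": float(sub.K_p.max()),
            "lambda_range": [float(sub["lambda"].min()), float(sub["lambda"].max())],
            "lambda_p_max": float(sub.lambda_p.max()),
        }
    _write_json(out / "signal_summary.json", summary)
    return df, summary


@_stage("correlations")
def _corr_stage(cfg: PipelineConfig, trees, diet_tv, mass_tv, out: Path):
    plain = nonphylo_correlation(dict(diet_tv.items()), mass_tv)
    nonphylo = {
        "pearson_r": plain.coefficient, "p_value": plain.p_value, "n": plain.n,
    }
    for pat in cfg.exclude:
        res = nonphylo_correlation(dict(diet_tv.items()), mass_tv, exclude=[pat])
        nonphylo[f"pearson_r_excluding_{pat}"] = res.coefficient
    _write_json(out / "nonphylo_correlation.json", nonphylo)

    rows = []
    trail_all = {}
    n_failed = 0
    for ti, tree in enumerate(trees):
        try:
            cs_d, _, trail_d = standardize_branches(dict(diet_tv.items()), tree, alpha=cfg.alpha)
            cs_m, _, trail_m = standardize_branches(mass_tv, tree, alpha=cfg.alpha)
        except ValidationError as exc:
            # no transform in the grid standardized this tree/trait: the
            # contrast test is not run for this tree (recorded, not fatal)
            log.warning("tree %d: %s", ti, exc)
            n_failed += 1
            rows.append(
                {
                    "tree_index": ti, "diet_transform": "failed",
                    "mass_transform": "failed",
                    "pearson_r": np.nan, "pearson_p": np.nan,
                    "kendall_tau": np.nan, "kendall_p": np.nan,
                }
            )
            trail_all[ti] = {"status": "unstandardized", "detail": str(exc)}
            continue
        # contrasts must come from identically transformed node sets: the
        # two traits may use different branch transforms, but topology (and
        # hence node identity) is shared
        res = contrast_correlation(cs_d, cs_m)
        rows.append(
            {
                "tree_index": ti,
                "diet_transform": f"{cs_d.transform[0]}:{cs_d.transform[1]}",
                "mass_transform": f"{cs_m.transform[0]}:{cs_m.transform[1]}",
                "pearson_r": res["pearson"].coefficient,
                "pearson_p": res["pearson"].p_value,
                "kendall_tau": res["kendall"].coefficient,
                "kendall_p": res["kendall"].p_value,
            }
        )
        trail_all[ti] = {"diet": trail_d, "mass": trail_m}
    df = pd.DataFrame(rows)
    df.to_csv(out / "pic_correlations.csv", index=False)
    ok = df.dropna(subset=["pearson_r"])
    if ok.empty:
        raise ValidationError("branch-length standardization failed on every tree")
    summary = {
        "pearson_r_range": [float(ok.pearson_r.min()), float(ok.pearson_r.max())],
        "prop_significant_alpha": float((ok.pearson_p < cfg.alpha).mean()),
        "n_trees_unstandardized": n_failed,
        "alpha": cfg.alpha,
    }
    _write_json(out / "pic_summary.json", summary)
    _write_json(out / "branch_transform_trail.json", trail_all)
    return nonphylo, df, summary


ALL_STAGES = ("models", "asr", "signal", "pic")


def run_pipeline(cfg: PipelineConfig, stages: Optional[Sequence[str]] = None) -> Dict:
    """Run the requested stages (default: all) and write the report bundle.

    Diet compilation and tree loading always run; ``stages`` selects among
    ``models``, ``asr``, ``signal`` and ``pic``.
    """
    cfg.validate()
    stages = tuple(stages) if stages is not None else ALL_STAGES
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValidationError(f"unknown pipeline stages: {sorted(unknown)}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    table, diet_tv, mass_tv = _compile_stage(cfg, out)
    trees, shared = _trees_stage(cfg, list(diet_tv.keys()))
    diet_tv = diet_tv.restrict(shared)
    mass_tv = {s: mass_tv[s] for s in shared}

    sel = asr_summary = signal_summary = nonphylo = pic_summary = None
    if "models" in stages or "asr" in stages:
        # ASR needs the per-tree lambda estimates from the model fits
        sel = _models_stage(cfg, trees, diet_tv, out)

    if "asr" in stages:
        consensus = strict_consensus(trees) if len(trees) > 1 else trees[0]
        if cfg.clades_file:
            raw = json.loads(Path(cfg.clades_file).read_text())
            clades = {lab: frozenset(tips) for lab, tips in raw.items()}
        else:
            clades = auto_consensus_nodes(consensus)
        asr_summary = _asr_stage(cfg, trees, diet_tv, sel, clades, out)
    if "signal" in stages:
        _, signal_summary = _signal_stage(cfg, trees, diet_tv, mass_tv, out)
    if "pic" in stages:
        nonphylo, pic_df, pic_summary = _corr_stage(cfg, trees, diet_tv, mass_tv, out)

    config_json = json.dumps(asdict(cfg), sort_keys=True, default=str)
    manifest = {
        "phylodiet_version": __version__,
        "config": json.loads(config_json),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "seed": cfg.seed,
        "n_trees": len(trees),
        "n_species": len(shared),
        "outputs": sorted(
            {p.name for p in out.iterdir() if p.is_file()} | {"manifest.json"}
        ),
    }
    _write_json(out / "manifest.json", manifest)
    return {
        "species_table": table,
        "model_selection": sel,
        "asr": asr_summary,
        "signal": signal_summary,
        "nonphylo": nonphylo,
        "pic": pic_summary,
        "manifest": manifest,
    }


def write_study(study, out_dir) -> Dict[str, str]:
    """Write a synthetic study bundle in the pipeline's input formats."""
    from .diet import entries_to_frame

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    df = entries_to_frame(study.diet_entries)
    paths["diet_table"] = str(out / "diet_entries.csv")
    df.to_csv(paths["diet_table"], index=False)
    mass = pd.DataFrame(
        {"species": list(study.body_mass_g), "body_mass_g": list(study.body_mass_g.values())}
    )
    paths["mass_table"] = str(out / "body_mass.csv")
    mass.to_csv(paths["mass_table"], index=False)
    paths["trees_file"] = str(out / "trees.nwk")
    with open(paths["trees_file"], "w") as fh:
        for t in study.tree_sample:
            fh.write(t.to_newick().replace("\n", "") + "\n")
    paths["clades_file"] = str(out / "clades.json")
    _write_json(Path(paths["clades_file"]), {k: sorted(v) for k, v in study.consensus_clades.items()})
    _write_json(
        out / "truth.json",
        {
            "true_H": study.true_H,
            "true_log10_mass": study.true_log10_mass,
            "herbivore_clades": [sorted(c) for c in study.herbivore_clades],
            "countertrend_species": study.countertrend_species,
            "seed": study.config.seed,
        },
    )
    return paths
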