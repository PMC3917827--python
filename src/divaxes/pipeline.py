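"""Configuration-driven orchestration of the three analysis axes.

A single YAML config resolves each data axis (climate, morphology,
sequence loci) either to input files or to a synthetic-generation block,
carries the permutation counts and every analysis toggle, and records
all seeds in a run manifest so reruns are bit-identical.
"""

from __future__ import annotations

import json
import logging
import traceback
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__, morpho, niche
from .popgen import (
    aa_profile,
    amova,
    kst_test,
    locus_stats,
    partition_from_sheet,
    read_alignment,
)
from .synthetic import (
    ClimateGenSpec,
    LocusSpec,
    MorphoGenSpec,
    SampleDesign,
    TraitParams,
    generate_climate_occurrences,
    generate_morphology,
    simulate_multilocus_dataset,
    study_locus_specs,
)

__all__ = ["load_config", "run_niche", "run_morpho", "run_popgen", "run_all"]

log = logging.getLogger("divaxes")

DEFAULT_PERMS = {"niche": 9999, "kst": 999, "amova": 100_000}
FAST_PERMS = {"niche": 999, "kst": 199, "amova": 999}
_FLOAT_FMT = "%.6g"


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def _perms(cfg: dict, key: str, fast: bool) -> int:
    base = FAST_PERMS if fast else DEFAULT_PERMS
    return int(cfg.get("n_permutations", {}).get(key, base[key]))


def _stage_seed(master_seed: int, stage: str) -> int:
    ss = np.random.SeedSequence([master_seed, abs(hash(stage)) % 2**31])
    return int(ss.generate_state(1)[0] % 2**31)


def _resolve_axis(block: dict, name: str) -> str:
    has_file = any(k in block for k in ("csv", "fasta"))
    has_synth = "synthetic" in block
    if has_file == has_synth:
        raise ValueError(
            f"{name}: exactly one of an input path or a synthetic block required"
        )
    return "file" if has_file else "synthetic"


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------- niche


def _climate_table(cfg: dict, seed: int) -> pd.DataFrame:
    block = cfg.get("climate", {})
    if _resolve_axis(block, "climate") == "file":
        return niche.load_climate_table(block["csv"])
    syn = dict(block["synthetic"])
    syn.setdefault("seed", seed)
    syn["n_per_group"] = tuple(syn.get("n_per_group", (28, 8)))
    syn["shift_vector"] = tuple(syn.get("shift_vector", (0.0,) * syn.get("n_latent", 3)))
    return generate_climate_occurrences(ClimateGenSpec(**syn))


def run_niche(cfg: dict, outdir: str | Path, fast: bool = False) -> dict:
    """PCA + per-axis Di permutation tests + Wilks MANOVA; writes TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    n_perm = _perms(cfg, "niche", fast)
    flags = cfg.get("flags", {})
    n_axes = int(cfg.get("climate", {}).get("n_axes", 3))

    table = _climate_table(cfg, _stage_seed(seed, "climate-data"))
    if table["group"].nunique() < 2:
        raise ValueError("climate table needs two group labels")
    pca = niche.standardize_and_pca(table, n_axes=n_axes)
    groups = table["group"].to_numpy()

    rows = []
    for axis in range(n_axes):
        res = niche.di_permutation_test(
            pca.scores,
            groups,
            axis,
            n_permutations=n_perm,
            seed=_stage_seed(seed, f"di-axis{axis}"),
            tail=flags.get("tail", "two-sided"),
            plus_one=bool(flags.get("plus_one", False)),
        )
        rows.append(
            {
                "axis": f"PC{axis + 1}",
                "variance_fraction": pca.variance_fraction[axis],
                "di_observed": res.di_observed,
                "p_value": res.p_value,
                "n_permutations": res.n_permutations,
                "seed": res.seed,
            }
        )
        if cfg.get("climate", {}).get("dump_null", False):
            pd.DataFrame({"di_null": res.null_sample}).to_csv(
                outdir / f"di_null_PC{axis + 1}.tsv", sep="\t", index=False,
                float_format=_FLOAT_FMT,
            )
    di_df = pd.DataFrame(rows)
    _write(di_df, outdir / "niche_di.tsv")

    loadings = pd.DataFrame(
        pca.loadings, index=pca.var_names,
        columns=[f"PC{i + 1}" for i in range(n_axes)],
    )
    loadings.index.name = "variable"
    loadings.reset_index().to_csv(
        outdir / "niche_loadings.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )

    man = niche.wilks_manova(pca.scores[:, :n_axes], groups)
    _write(
        pd.DataFrame(
            [
                {
                    "wilks_lambda": man.wilks_lambda,
                    "approx_F": man.approx_F,
                    "df1": man.df[0],
                    "df2": man.df[1],
                    "p_value": man.p_value,
                }
            ]
        ),
        outdir / "niche_manova.tsv",
    )
    log.info("niche: %d sites, %d axes, %d permutations", len(table), n_axes, n_perm)
    return {"di": di_df, "manova": man, "pca": pca}


# --------------------------------------------------------------- morpho


def _morphology_table(cfg: dict, seed: int) -> pd.DataFrame:
    block = cfg.get("morphology", {})
    if _resolve_axis(block, "morphology") == "file":
        df = pd.read_csv(block["csv"])
        required = {"individual_id", "site_id", "group", "sex", "mass", "wing", "tarsus"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"morphology table missing columns {sorted(missing)}")
        return df
    syn = dict(block["synthetic"])
    syn.setdefault("seed", seed)
    if "sites" in syn:
        syn["sites"] = tuple(tuple(s) for s in syn["sites"])
    else:
        # 12 sites spanning a climate gradient, two groups
        rng = np.random.default_rng(seed)
        xs = np.linspace(-2.5, 2.5, 12) + rng.normal(scale=0.1, size=12)
        syn["sites"] = tuple(
            (f"site{i + 1:02d}", "group1" if i < 8 else "group2", float(x))
            for i, x in enumerate(xs)
        )
    if "traits" in syn:
        syn["traits"] = {k: TraitParams(**v) for k, v in syn["traits"].items()}
    return generate_morphology(MorphoGenSpec(**syn))


def _site_scores(cfg: dict, table: pd.DataFrame, seed: int) -> pd.DataFrame:
    block = cfg.get("morphology", {})
    if "site_scores" in block:
        scores = pd.read_csv(block["site_scores"])
        orphans = sorted(set(table["site_id"]) - set(scores["site_id"]))
        if orphans:
            raise ValueError(f"morphology sites without climate scores: {orphans}")
        return scores
    if "climate_axis" in table.columns:
        # synthetic generator: its axis plays the role of PC2 (the
        # temperate–tropical gradient); PC1 is an independent site axis
        rng = np.random.default_rng(seed)
        sites = table[["site_id", "climate_axis"]].drop_duplicates("site_id")
        return pd.DataFrame(
            {
                "site_id": sites["site_id"].to_numpy(),
                "pc1": rng.standard_normal(len(sites)),
                "pc2": sites["climate_axis"].to_numpy(),
            }
        )
    raise ValueError("no site-level climate scores resolvable for morphology")


def run_morpho(cfg: dict, outdir: str | Path, fast: bool = False) -> dict:
    """Factorial ANOVA per trait + the four-model AICc suite (Table-1 shape)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    flags = cfg.get("flags", {})

    raw = _morphology_table(cfg, _stage_seed(seed, "morpho-data"))
    scores = _site_scores(cfg, raw, _stage_seed(seed, "morpho-scores"))
    table = morpho.preprocess(raw)
    # site-level n>=3 rule for site-structured analyses
    counts = table.groupby("site_id")["individual_id"].count()
    keep = counts[counts >= 3].index
    table = table[table["site_id"].isin(keep)].reset_index(drop=True)
    table["size"] = morpho.size_index(table)
    table = table.merge(scores, on="site_id", validate="many_to_one")

    anova_rows = []
    for trait in ("mass", "wing", "tarsus", "size"):
        tab = morpho.factorial_anova(
            table, trait, ss_type=int(flags.get("ss_type", 2))
        )
        for term, row in tab.iterrows():
            if term == "Residual":
                continue
            anova_rows.append(
                {
                    "trait": trait,
                    "term": term,
                    "F": row["F"],
                    "p_value": row["PR(>F)"],
                }
            )
    anova_df = pd.DataFrame(anova_rows)
    _write(anova_df, outdir / "morpho_anova.tsv")

    model_rows = []
    for trait in ("mass", "wing", "tarsus", "size"):
        comp = morpho.fit_climate_models(table[trait], table["pc1"], table["pc2"])
        comp.insert(0, "trait", trait)
        model_rows.append(comp)
    models_df = pd.concat(model_rows, ignore_index=True)
    _write(models_df, outdir / "morpho_models.tsv")
    log.info("morpho: %d individuals, %d model rows", len(table), len(models_df))
    return {"anova": anova_df, "models": models_df, "table": table}


# --------------------------------------------------------------- popgen


def _loci_and_sheet(cfg: dict, seed: int, outdir: Path):
    block = cfg.get("loci", {})
    if _resolve_axis(block, "loci") == "file":
        sheet = pd.read_csv(block["sample_sheet"], sep="\t")
        alns = [read_alignment(p) for p in block["fasta"]]
        return alns, sheet
    syn = dict(block.get("synthetic", {}))
    specs = (
        [LocusSpec(**ls) for ls in syn["locus_specs"]]
        if "locus_specs" in syn
        else study_locus_specs()
    )
    design = SampleDesign(**{
        k: tuple(v) if isinstance(v, list) else v
        for k, v in syn.get("design", {}).items()
    })
    ds = simulate_multilocus_dataset(
        specs,
        design,
        split_time=float(syn.get("split_time", 2.0)),
        mig_12=float(syn.get("mig_12", 0.0)),
        mig_21=float(syn.get("mig_21", 0.0)),
        seed=syn.get("seed", seed),
        outdir=outdir / "simulated_loci",
    )
    alns = [
        read_alignment(outdir / "simulated_loci" / f"{name}.fasta")
        for name in ds.loci
    ]
    return alns, ds.sample_sheet


def run_popgen(cfg: dict, outdir: str | Path, fast: bool = False) -> dict:
    """Per-locus diversity stats, Kst tests and a two-level AMOVA."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    flags = cfg.get("flags", {})
    kst_perm = _perms(cfg, "kst", fast)
    amova_perm = _perms(cfg, "amova", fast)

    alns, sheet = _loci_and_sheet(cfg, _stage_seed(seed, "loci-data"), outdir)
    if not alns:
        raise ValueError("no loci resolvable")

    stat_rows = []
    kst_rows = []
    for aln in alns:
        part_group = partition_from_sheet(sheet, aln.sequence_ids, level="group")
        overall = locus_stats(aln)
        groups = sorted(set(part_group.seq_to_pop.values()))
        row: dict[str, Any] = {
            "locus": aln.name,
            "n": overall.n,
            "sites_bp": overall.L,
        }
        for g in groups:
            ids = [s for s in aln.sequence_ids if part_group.seq_to_pop[s] == g]
            st = locus_stats(aln.subset(ids))
            row.update(
                {
                    f"S_{g}": st.S,
                    f"Hd_{g}": st.Hd,
                    f"theta_{g}": st.theta_w_site,
                    f"theta_se_{g}": st.theta_w_se,
                    f"TD_{g}": st.tajimas_d,
                }
            )
        row["TD_overall"] = overall.tajimas_d
        stat_rows.append(row)

        kst = kst_test(
            aln,
            part_group,
            n_permutations=kst_perm,
            seed=_stage_seed(seed, f"kst-{aln.name}"),
            weighting=flags.get("kst_weighting", "n"),
        )
        kst_rows.append(
            {
                "locus": aln.name,
                "kst": kst.kst,
                "p_value": kst.p_value,
                "n_permutations": kst.n_permutations,
            }
        )
    _write(pd.DataFrame(stat_rows), outdir / "popgen_locus_stats.tsv")
    _write(pd.DataFrame(kst_rows), outdir / "popgen_kst.tsv")

    # AMOVA on the first locus with populations nested in groups
    target = alns[0]
    part_pop = partition_from_sheet(sheet, target.sequence_ids, level="population")
    am = amova(
        target,
        part_pop,
        n_permutations=amova_perm,
        seed=_stage_seed(seed, "amova"),
    )
    _write(
        pd.DataFrame(
            [
                {
                    "locus": target.name,
                    "sigma_among_groups": am.sigma_a,
                    "sigma_among_pops": am.sigma_b,
                    "sigma_within_pops": am.sigma_c,
                    "pct_among_groups": am.percentages[0],
                    "pct_among_pops": am.percentages[1],
                    "pct_within_pops": am.percentages[2],
                    "F_CT": am.f_ct,
                    "F_SC": am.f_sc,
                    "F_ST": am.f_st,
                    "p_F_CT": am.p_f_ct,
                    "p_F_SC": am.p_f_sc,
                    "p_F_ST": am.p_f_st,
                    "n_permutations": am.n_permutations,
                }
            ]
        ),
        outdir / "popgen_amova.tsv",
    )

    result: dict[str, Any] = {
        "stats": pd.DataFrame(stat_rows),
        "kst": pd.DataFrame(kst_rows),
        "amova": am,
    }
    aa_cfg = cfg.get("loci", {}).get("aa_profile")
    if aa_cfg:
        target = next(a for a in alns if a.name == aa_cfg["locus"])
        part = partition_from_sheet(sheet, target.sequence_ids, level="group")
        prof = aa_profile(target, part, frame=int(aa_cfg.get("frame", 0)))
        _write(
            pd.DataFrame(
                [
                    {
                        "codon_position": s.codon_position,
                        "amino_acids": "/".join(s.amino_acids),
                        "diagnostic": s.diagnostic,
                    }
                    for s in prof.sites
                ]
            ),
            outdir / "popgen_aa_profile.tsv",
        )
        result["aa_profile"] = prof
    log.info("popgen: %d loci", len(alns))
    return result


# ----------------------------------------------------------------- all


def run_all(cfg: dict, outdir: str | Path, fast: bool = False) -> dict:
    """Run every resolvable stage; keep completed stages on partial failure."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": int(cfg.get("seed", 0)),
        "fast": fast,
        "flags": cfg.get("flags", {}),
        "n_permutations": {
            k: _perms(cfg, k, fast) for k in ("niche", "kst", "amova")
        },
        "stages": {},
    }
    results: dict[str, Any] = {}
    stages = {
        "niche": (run_niche, "climate"),
        "morpho": (run_morpho, "morphology"),
        "popgen": (run_popgen, "loci"),
    }
    for name, (fn, axis) in stages.items():
        if axis not in cfg:
            manifest["stages"][name] = {"status": "skipped (no config)"}
            continue
        try:
            results[name] = fn(cfg, outdir, fast=fast)
            manifest["stages"][name] = {"status": "ok"}
        except Exception as exc:  # noqa: BLE001 — manifest records the failure
            log.error("stage %s failed: %s", name, exc)
            manifest["stages"][name] = {
                "status": "failed",
                "error": str(exc),
                "traceback": traceback.format_exc(),
            }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    results["manifest"] = manifest
    return results
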