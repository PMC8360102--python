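"""Config-driven end-to-end asymmetry analysis.

Workflow (mirroring the standard object-symmetry protocol): load or
simulate originals -> build the doubled dataset (originals + reflected,
relabelled copies) -> generalized Procrustes superimposition (optionally
with semilandmark sliding) -> Procrustes distance matrix -> dispersion
homogeneity and PERMANOVA of collection within each age group (the pooling
gate) -> symmetry decomposition -> per-group Procrustes ANOVA -> per-
landmark DA/FA tables -> between-group ANOVAs with Tukey HSD -> Spearman
correlation of DA profiles -> Kruskal-Wallis + Dunn across landmarks ->
per-landmark FA Kruskal-Wallis with Bonferroni correction -> Mann-Whitney
sex comparisons for the adult groups.  Every stage writes a TSV table and
the run log records config, seeds and warnings.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import asymmetry as asym
from . import stats as st
from .io import read_landmarks, write_landmarks, write_table
from .procrustes import SlideOptions, distance_matrix, gpa
from .schema import AGE_GROUPS, PopulationDataset, default_palate_schema
from .simulate import SimulationSpec, simulate_population

__all__ = ["RunConfig", "run", "report"]


@dataclass
class RunConfig:
    """Pipeline configuration.

    Exactly one of ``input_path`` (landmark file) or ``simulation``
    (generator spec) must be set.
    """

    input_path: str | None = None
    input_format: str = "csv"
    simulation: SimulationSpec | None = None
    gpa_mode: str = "pooled"  # pooled | per_group
    sliding: bool = False
    slide_options: SlideOptions = field(default_factory=SlideOptions)
    n_perm: int = 999
    seed: int = 0
    out_dir: str = "palasym_run"
    make_figures: bool = False

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.simulation is None):
            raise ValueError("set exactly one of input_path / simulation")
        if self.gpa_mode not in ("pooled", "per_group"):
            raise ValueError("gpa_mode must be 'pooled' or 'per_group'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        sim = doc.pop("simulation", None)
        slide = doc.pop("slide_options", None)
        cfg = cls(
            simulation=SimulationSpec(**{k: tuple(v) if isinstance(v, list) else v for k, v in sim.items()}) if sim is not None else None,
            slide_options=SlideOptions(**slide) if slide else SlideOptions(),
            **doc,
        )
        return cfg

    def to_jsonable(self) -> dict:
        doc = asdict(self)
        return doc


def _seed_stream(seed: int):
    ss = np.random.SeedSequence(seed)
    while True:
        (child,) = ss.spawn(1)
        ss = child
        yield int(child.generate_state(1)[0] % (2**31 - 1))


def _group_order(groups) -> list[str]:
    known = [g for g in AGE_GROUPS if g in groups]
    extra = sorted(set(groups) - set(known))
    return known + extra


def run(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _seed_stream(config.seed)
    log: dict = {
        "version": __version__,
        "config": config.to_jsonable(),
        "seed": config.seed,
        "warnings": [],
        "stages": [],
    }

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        # ---- load / simulate ------------------------------------------------
        if config.simulation is not None:
            sim_spec = config.simulation
            if sim_spec.seed != config.seed:
                sim_spec = SimulationSpec(**{**asdict(sim_spec), "seed": config.seed})
            dataset = simulate_population(sim_spec)
            write_landmarks(dataset, out / "simulated_landmarks.csv", "csv")
            if dataset.ground_truth is not None:
                dataset.ground_truth.write(out / "ground_truth.json")
        else:
            dataset = read_landmarks(config.input_path, config.input_format)
        problems = dataset.validate()
        if problems:
            raise ValueError(f"stage=load: invalid dataset: {problems[:5]}")
        log["stages"].append({"stage": "load", "n_individuals": len(dataset)})

        # ---- doubled dataset + GPA -----------------------------------------
        doubled = asym.build_symmetry_dataset(dataset)
        slide = config.slide_options if config.sliding else None
        fit = gpa(doubled, slide=slide, schema=doubled.schema)
        log["stages"].append(
            {
                "stage": "gpa",
                "n_configurations": len(doubled),
                "iterations": fit.n_iterations,
                "converged": bool(fit.converged),
            }
        )

        groups_present = _group_order({c.age_group for c in dataset.configurations})

        # ---- pooling gate: collection effect within each age group ---------
        pool_rows = []
        orig_idx = [
            i for i, c in enumerate(doubled.configurations) if not c.is_reflected_copy
        ]
        D_orig = distance_matrix(fit.aligned[orig_idx])
        metas = [doubled.configurations[i] for i in orig_idx]
        for g in groups_present:
            gi = [j for j, c in enumerate(metas) if c.age_group == g]
            colls = np.array([metas[j].collection for j in gi])
            if len(set(colls.tolist())) < 2 or min(np.bincount(np.unique(colls, return_inverse=True)[1])) < 2:
                pool_rows.append(
                    {"group": g, "n": len(gi), "betadisper_F": np.nan, "betadisper_p": np.nan,
                     "permanova_F": np.nan, "permanova_Rsq": np.nan, "permanova_p": np.nan,
                     "note": "collection comparison not estimable"}
                )
                continue
            Dg = D_orig[np.ix_(gi, gi)]
            disp = st.dispersion_homogeneity(Dg, colls, n_perm=config.n_perm, seed=next(seeds))
            perma = st.permanova(Dg, colls, n_perm=config.n_perm, seed=next(seeds))
            pool_rows.append(
                {"group": g, "n": len(gi), "betadisper_F": disp.f, "betadisper_p": disp.p,
                 "permanova_F": perma.f, "permanova_Rsq": perma.rsq, "permanova_p": perma.p,
                 "note": ""}
            )
        pool_df = pd.DataFrame(pool_rows)
        write_table(pool_df, out / "collection_pooling.tsv")
        estimable = pool_df["permanova_p"].dropna()
        pooled_ok = bool((estimable > 0.05).all()) if len(estimable) else True
        log["pooling_gate"] = {
            "rule": "collections are pooled when no age group shows a significant "
                    "collection effect (PERMANOVA p > 0.05)",
            "fired": not pooled_ok,
        }
        log["stages"].append({"stage": "pooling_gate", "pooled": pooled_ok})

        # ---- symmetry decomposition ----------------------------------------
        if config.gpa_mode == "pooled":
            decompositions = {"pooled": (fit, doubled)}
        else:
            decompositions = {}
            for g in groups_present:
                idx = [i for i, c in enumerate(doubled.configurations) if c.age_group == g]
                sub = PopulationDataset(
                    schema=doubled.schema,
                    configurations=[doubled.configurations[i] for i in idx],
                )
                decompositions[g] = (gpa(sub, slide=slide, schema=sub.schema), sub)

        all_groups: dict[str, asym.GroupAsymmetry] = {}
        all_individuals: list[asym.IndividualAsymmetry] = []
        for key, (f_, d_) in decompositions.items():
            _, individuals, groups = asym.decompose(f_, d_)
            all_groups.update(groups)
            all_individuals.extend(individuals)
        all_individuals.sort(key=lambda i: (groups_present.index(i.age_group), i.individual_id))
        log["stages"].append({"stage": "decompose", "groups": {g: all_groups[g].n for g in groups_present}})

        # ---- per-group Procrustes ANOVA (within-group shape variation) -----
        t3_rows = []
        for key, (f_, d_) in decompositions.items():
            for g in groups_present if key == "pooled" else [key]:
                o_idx = [i for i, c in enumerate(d_.configurations)
                         if c.age_group == g and not c.is_reflected_copy]
                r_map = {c.individual_id: i for i, c in enumerate(d_.configurations)
                         if c.age_group == g and c.is_reflected_copy}
                o_ids = [d_.configurations[i].individual_id for i in o_idx]
                O = f_.aligned[o_idx]
                R = f_.aligned[[r_map[i] for i in o_ids]]
                tab = st.procrustes_anova_symmetry(O, R, n_perm=config.n_perm, seed=next(seeds))
                tab.insert(0, "group", g)
                t3_rows.append(tab)
        table3 = pd.concat(t3_rows, ignore_index=True)
        write_table(table3, out / "table3_within_group_anova.tsv")

        # ---- per-landmark DA / FA tables -----------------------------------
        da_long, fa_long = asym.per_landmark_tables(all_groups, all_individuals, dataset.schema)
        da_long["group"] = pd.Categorical(da_long["group"], categories=groups_present, ordered=True)
        da_long = da_long.sort_values(["group", "landmark_id"]).reset_index(drop=True)
        write_table(da_long, out / "da_per_landmark.tsv")
        write_table(fa_long, out / "fa_per_landmark.tsv")

        # ---- between-group ANOVAs + Tukey ----------------------------------
        da_vals = da_long["da"].to_numpy()
        da_lab = da_long["group"].astype(str).to_numpy()
        table4 = st.oneway_anova(da_vals, da_lab)
        table4.loc[table4["effect"] == "group", "effect"] = "DA.group"
        write_table(table4, out / "table4_da_between_groups.tsv")
        write_table(st.tukey_hsd(da_vals, da_lab), out / "table5_da_tukey.tsv")

        fa_mean = fa_long  # one observation per individual x landmark
        fa_vals = fa_mean["fa"].to_numpy()
        fa_lab = fa_mean["group"].astype(str).to_numpy()
        table8 = st.oneway_anova(fa_vals, fa_lab)
        table8.loc[table8["effect"] == "group", "effect"] = "FA.group"
        write_table(table8, out / "table8_fa_between_groups.tsv")
        write_table(st.tukey_hsd(fa_vals, fa_lab), out / "table9_fa_tukey.tsv")

        # ---- Spearman correlation of DA profiles ---------------------------
        da_wide = da_long.pivot_table(index="group", columns="landmark_id", values="da", observed=True)
        da_wide = da_wide.loc[groups_present]
        spearman = st.spearman_matrix(da_wide)
        sp_rows = [
            {"group_a": ga, "group_b": gb, "rho": float(spearman.loc[ga, gb])}
            for i, ga in enumerate(groups_present)
            for gb in groups_present[:i]
        ]
        write_table(pd.DataFrame(sp_rows), out / "table6_da_spearman.tsv")

        # ---- DA across landmarks: Kruskal-Wallis + Dunn --------------------
        lm_lab = da_long["landmark_id"].astype(str).to_numpy()
        h, dfkw, pkw = st.kruskal_wallis(da_vals, lm_lab)
        dunn = st.dunn_posthoc(da_vals, lm_lab, adjust="bonferroni")
        dunn.insert(0, "test", "DA_across_landmarks")
        write_table(dunn, out / "table7_da_dunn.tsv")
        log["stages"].append(
            {"stage": "kw_da_landmarks", "H": h, "df": dfkw, "p": pkw, "n_pairs": len(dunn)}
        )

        # ---- per-landmark FA: Kruskal-Wallis with Bonferroni ---------------
        kw_rows = []
        for lid, sub in fa_long.groupby("landmark_id"):
            h_l, df_l, p_l = st.kruskal_wallis(sub["fa"].to_numpy(), sub["group"].astype(str).to_numpy())
            kw_rows.append({"landmark_id": lid, "H": h_l, "df": df_l, "p_unadj": p_l})
        kw_df = pd.DataFrame(kw_rows)
        kw_df["p_adj"] = st.bonferroni(kw_df["p_unadj"].to_numpy())
        write_table(kw_df, out / "fa_per_landmark_kw.tsv")

        # ---- sex comparisons (adult groups only) ---------------------------
        sex_rows = []
        ind_by_group: dict[str, list[asym.IndividualAsymmetry]] = {}
        for ind in all_individuals:
            ind_by_group.setdefault(ind.age_group, []).append(ind)
        for g in groups_present:
            if g in ("I", "II", "III"):
                log["warnings"].append(
                    f"sex comparison skipped for group {g} (sexual traits absent/uncertain)"
                )
                continue
            members = [i for i in ind_by_group.get(g, []) if i.sex in ("M", "F")]
            m = [i for i in members if i.sex == "M"]
            f_ = [i for i in members if i.sex == "F"]
            if len(m) < 2 or len(f_) < 2:
                continue
            # sex-specific DA profiles: per-landmark norms of the sex-mean
            # asymmetry vector, compared across the 41 landmarks
            da_m = np.sqrt((np.mean([i.asym_vector for i in m], axis=0) ** 2).sum(axis=1))
            da_f = np.sqrt((np.mean([i.asym_vector for i in f_], axis=0) ** 2).sum(axis=1))
            u, p, meth = st.mann_whitney(da_m, da_f)
            sex_rows.append({"group": g, "measure": "DA", "U": u, "p": p, "method": meth,
                             "n_M": len(m), "n_F": len(f_)})
            # per-landmark mean FA profiles by sex
            fa_m = np.mean([i.fa_per_landmark for i in m], axis=0)
            fa_f = np.mean([i.fa_per_landmark for i in f_], axis=0)
            u, p, meth = st.mann_whitney(fa_m, fa_f)
            sex_rows.append({"group": g, "measure": "FA", "U": u, "p": p, "method": meth,
                             "n_M": len(m), "n_F": len(f_)})
        write_table(pd.DataFrame(sex_rows, columns=["group", "measure", "U", "p", "method", "n_M", "n_F"]),
                    out / "sex_mann_whitney.tsv")

        log["warnings"].extend(str(w.message) for w in caught)

    (out / "runlog.json").write_text(json.dumps(log, indent=1, default=str))
    if config.make_figures:
        report(out)
    return out


def report(run_dir: str | Path) -> list[Path]:
    """Render summary figures from a run directory's TSV tables.

    Missing tables are listed in the returned log, not fatal.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run_dir = Path(run_dir)
    made: list[Path] = []

    da_path = run_dir / "da_per_landmark.tsv"
    if da_path.exists():
        da = pd.read_csv(da_path, sep="\t")
        fig, ax = plt.subplots(figsize=(10, 4))
        for g, sub in da.groupby("group", sort=False):
            ax.plot(sub["landmark_id"], sub["da"], label=f"group {g}")
        ax.set_xlabel("landmark id")
        ax.set_ylabel("DA (Procrustes units)")
        ax.set_title("Directional asymmetry per landmark")
        ax.legend(fontsize=8)
        p = run_dir / "fig_da_per_landmark.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        made.append(p)

    fa_path = run_dir / "fa_per_landmark.tsv"
    if fa_path.exists():
        fa = pd.read_csv(fa_path, sep="\t")
        fig, ax = plt.subplots(figsize=(10, 4))
        for g, sub in fa.groupby("group", sort=False):
            agg = sub.groupby("landmark_id")["fa"]
            mean = agg.mean()
            se = agg.sem().fillna(0.0)
            ax.plot(mean.index, mean.values, label=f"group {g}")
            ax.fill_between(mean.index, mean - 1.96 * se, mean + 1.96 * se, alpha=0.15)
        ax.set_xlabel("landmark id")
        ax.set_ylabel("mean FA (Procrustes units)")
        ax.set_title("Fluctuating asymmetry per landmark (mean, 95% envelope)")
        ax.legend(fontsize=8)
        p = run_dir / "fig_fa_per_landmark.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        made.append(p)

    sex_path = run_dir / "sex_mann_whitney.tsv"
    if sex_path.exists():
        sx = pd.read_csv(sex_path, sep="\t")
        if len(sx):
            fig, ax = plt.subplots(figsize=(6, 4))
            for meas, sub in sx.groupby("measure"):
                ax.plot(sub["group"], sub["p"], marker="o", label=meas)
            ax.axhline(0.05, color="grey", ls="--", lw=0.8)
            ax.set_xlabel("age group")
            ax.set_ylabel("Mann-Whitney p (M vs F)")
            ax.set_title("Sex comparisons")
            ax.legend()
            p = run_dir / "fig_sex_comparison.png"
            fig.savefig(p, dpi=120)
            plt.close(fig)
            made.append(p)
    return made
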