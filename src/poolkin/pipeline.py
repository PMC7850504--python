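"""End-to-end pipeline: filter -> diversity -> structure -> distances ->
ordination -> f3 -> spatial, with seeded stages and provenance headers.

A :class:`RunConfig` is the single source of truth for a run; it
round-trips through YAML so a completed analysis can be replayed
byte-identically.  Inputs are either paths to the CSV/TSV formats the
io_core readers consume or a synthetic preset generated on the fly.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diversity as dv
from . import distances as ds
from . import f3 as f3mod
from . import io_core as io
from . import ordination as ordn
from . import simulate as sim
from . import spatial as sp
from . import structure as st

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending input."""


@dataclass
class RunConfig:
    # inputs: either explicit paths ...
    frequency_path: str | None = None
    passport_path: str | None = None
    marker_path: str | None = None
    # ... or a synthetic preset ("swf-panel" scaled by preset_scale)
    synthetic_preset: str | None = None
    preset_scale: float = 1.0
    n_loci: int | None = None

    out_dir: str = "poolkin_run"
    seed: int = 0

    # stage toggles
    run_structure: bool = True
    run_f3: bool = True
    run_spatial: bool = True

    # module parameters
    drop_monomorphic: bool = False
    monomorphic_eps: float = 0.0
    n_windows: int = 2500
    n_haploid_reps: int = 5
    k_min: int = 1
    k_max: int = 6
    structure_replicates: int = 3
    em_tol: float = 1e-6
    em_max_iter: int = 500
    purity_cutoff: float = 0.7
    f3_block_size: int = 500
    n_perm: int = 999
    rarefy_g: int = 9
    rarefy_resamples: int = 1000

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _load_inputs(cfg: RunConfig):
    if cfg.synthetic_preset is not None:
        if cfg.synthetic_preset != "swf-panel":
            raise PipelineError(f"unknown synthetic preset {cfg.synthetic_preset!r}")
        sim_cfg = sim.swf_panel_config(seed=cfg.seed, scale=cfg.preset_scale)
        if cfg.n_loci is not None:
            sim_cfg.n_loci = cfg.n_loci
        fm_ref, pp_ref, _ = sim.generate_reference_panel(sim_cfg)
        fm_swf, pp_swf, panel = sim.generate_swf_gradient(sim_cfg)
        values = np.vstack([fm_swf.values, fm_ref.values])
        fm = io.FrequencyMatrix(fm_swf.landrace_ids + fm_ref.landrace_ids,
                                panel.locus_ids, values)
        pp = io.PassportTable(pd.concat([pp_swf.table.drop(columns=["has_coordinates"]),
                                         pp_ref.table.drop(columns=["has_coordinates"])],
                                        ignore_index=True))
        return fm, pp, panel, fm_swf.landrace_ids
    for name, path in (("frequency", cfg.frequency_path),
                       ("passport", cfg.passport_path),
                       ("marker map", cfg.marker_path)):
        if path is None or not Path(path).exists():
            raise PipelineError(f"stage 'load': missing {name} input {path!r}")
    fm = io.read_frequency_matrix(cfg.frequency_path)
    pp = io.read_passport(cfg.passport_path)
    panel = io.read_marker_panel(cfg.marker_path)
    return fm, pp, panel, list(fm.landrace_ids)


def _write_with_header(df: pd.DataFrame, path: Path, cfg: RunConfig,
                       stage: str, **extra) -> None:
    with open(path, "w") as fh:
        fh.write(f"# stage={stage}\n# config_hash={cfg.config_hash()}\n"
                 f"# seed={cfg.seed}\n")
        for k, v in extra.items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, index=False)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every enabled stage; returns the summary report dictionary.

    Stage outputs are CSV files under ``cfg.out_dir`` with provenance
    headers (stage, config hash, seed).  Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    report: dict = {"config_hash": cfg.config_hash(), "seed": cfg.seed,
                    "stages": {}}
    t0 = time.time()

    def stage(name):
        def wrap(fn):
            start = time.time()
            try:
                fn()
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            report["stages"][name] = round(time.time() - start, 3)
        return wrap

    state: dict = {}

    @stage("load")
    def _load():
        fm, pp, panel, focal_ids = _load_inputs(cfg)
        state.update(fm=fm, pp=pp, panel=panel, focal_ids=focal_ids)

    @stage("filter")
    def _filter():
        fm, rep = io.filter_missing_loci(state["fm"])
        mono = io.detect_monomorphic(fm, cfg.monomorphic_eps)
        if cfg.drop_monomorphic and mono:
            fm, _ = io.drop_loci(fm, mono)
        state["fm"] = fm
        state["panel"] = state["panel"].subset(fm.locus_ids)
        report["filter"] = {"n_input": rep.n_input, "n_dropped": rep.n_dropped,
                            "n_retained": rep.n_retained,
                            "n_monomorphic": len(mono),
                            "monomorphic_dropped": cfg.drop_monomorphic}

    @stage("diversity")
    def _diversity():
        fm = state["fm"]
        recs = dv.diversity_table(fm)
        df = pd.DataFrame([{"landrace_id": r.landrace_id, "Ar": r.Ar,
                            "He": r.He, "prop_poly": r.prop_poly} for r in recs])
        _write_with_header(df, out / "diversity_landrace.csv", cfg, "diversity")
        report["diversity"] = {"mean_He": float(df["He"].mean()),
                               "mean_Ar": float(df["Ar"].mean())}

    @stage("distances")
    def _distances():
        fm = state["fm"]
        rogers = ds.pairwise_matrix(fm, "modified_rogers")
        rogers.write_csv(out / "rogers_distance.csv",
                         {"config_hash": cfg.config_hash()})
        state["rogers"] = rogers

    @stage("ordination")
    def _ordination():
        res = ordn.pcoa(state["rogers"], n_axes=5)
        state["pcoa"] = res
        df = pd.DataFrame(res.coordinates,
                          columns=[f"axis{i+1}" for i in range(res.coordinates.shape[1])])
        df.insert(0, "landrace_id", res.sample_ids)
        _write_with_header(df, out / "pcoa_coordinates.csv", cfg, "ordination")
        tree = ordn.neighbor_joining(state["rogers"])
        (out / "nj_tree.nwk").write_text(ordn.write_newick(tree) + "\n")
        report["ordination"] = {
            "pcoa_inertia_axis1_pct": float(res.percent_inertia[0]),
            "pcoa_inertia_axis2_pct": float(res.percent_inertia[1]),
        }

    @stage("structure")
    def _structure():
        if not cfg.run_structure:
            return
        fm = state["fm"].select_landraces(state["focal_ids"])
        thinned = st.thin_by_windows(state["panel"].subset(fm.locus_ids),
                                     cfg.n_windows, seed=cfg.seed)
        hp = st.simulate_haploids(fm.select_loci(thinned), cfg.n_haploid_reps,
                                  seed=cfg.seed + 1)
        best, lt = st.structure_scan(hp, range(cfg.k_min, cfg.k_max + 1),
                                     cfg.structure_replicates, seed=cfg.seed + 2,
                                     tol=cfg.em_tol, max_iter=cfg.em_max_iter)
        if cfg.k_max - cfg.k_min >= 2:
            dk = st.evanno_deltak(lt)
            chosen = st.best_k(dk)
            _write_with_header(dk, out / "structure_deltak.csv", cfg, "structure")
            dk_report = dk.set_index("K")["delta_k"].to_dict()
        else:
            # delta-K needs >= 3 K values; fall back to best mean loglik
            chosen = int(lt.mean_sd()["mean"].idxmax())
            dk_report = {}
        assign = st.assign_groups(best[chosen], cfg.purity_cutoff)
        _write_with_header(lt.table, out / "structure_loglik.csv", cfg, "structure")
        _write_with_header(assign, out / "structure_assignment.csv", cfg,
                           "structure", K=chosen)
        qdf = pd.DataFrame(best[chosen].Q_landrace,
                           columns=[f"Q{k+1}" for k in range(chosen)])
        qdf.insert(0, "landrace_id", best[chosen].landrace_ids)
        _write_with_header(qdf, out / "structure_Q.csv", cfg, "structure", K=chosen)
        state["assignment"] = assign
        state["chosen_k"] = chosen
        report["structure"] = {"chosen_K": chosen,
                               "delta_k": dk_report,
                               "n_thinned_loci": len(thinned)}

    @stage("group_fst")
    def _group_fst():
        if "assignment" not in state:
            return
        fm = state["fm"]
        assign = state["assignment"]
        clusters = assign.groupby("cluster")["landrace_id"].apply(list)
        if len(clusters) < 2:
            return
        ids0, ids1 = clusters.iloc[0], clusters.iloc[1]
        res, p = ds.fst_permutation_test(fm, ids0, ids1, n_perm=max(cfg.n_perm, 99),
                                         seed=cfg.seed + 3)
        report["group_fst"] = {"fst": res.Fst, "p_value": p,
                               "n_group0": len(ids0), "n_group1": len(ids1)}

    @stage("f3")
    def _f3():
        if not cfg.run_f3:
            return
        pp = state["pp"]
        try:
            groups = pp.groups("group")
        except KeyError:
            return
        ref_labels = [g for g in groups if g != "SWF" and len(groups[g]) >= 2]
        if "assignment" in state and len(ref_labels) >= 2:
            assign = state["assignment"]
            pure = assign[assign["is_pure"]]
            membership = {f"SWF_K{k}": grp["landrace_id"].tolist()
                          for k, grp in pure.groupby("cluster")
                          if len(grp) >= 1}
            membership.update({g: groups[g] for g in ref_labels})
            focal = [g for g in membership if g.startswith("SWF_K")]
            if focal:
                # keep >= 20 jackknife blocks on small panels
                block = min(cfg.f3_block_size,
                            max(state["fm"].n_loci // 20, 1))
                table = f3mod.scan_admixture_scenarios(
                    state["fm"], membership, focal, ref_labels,
                    block, panel=state["panel"])
                _write_with_header(table, out / "f3_scan.csv", cfg, "f3")
                sig = table[table["significant"]]
                report["f3"] = {"n_tests": len(table),
                                "n_significant": int(len(sig)),
                                "min_Z": float(table["Z"].min())}

    @stage("spatial")
    def _spatial():
        if not cfg.run_spatial:
            return
        pp = state["pp"]
        coords = pp.coordinates()
        ids = [i for i in state["focal_ids"] if i in coords.index]
        if len(ids) < 4:
            return
        fm = state["fm"].select_landraces(ids)
        geo = ds.geographic_matrix(
            io.PassportTable(pp.table[pp.table["landrace_id"].isin(ids)]))
        fst = ds.pairwise_matrix(fm, "fst_nei")
        lin = ds.DistanceMatrix(fst.ids, ds.linearize_fst(fst.values),
                                "linearized_fst")
        geo = geo.submatrix(lin.ids)
        ibd = sp.mantel_test(lin, geo, n_perm=cfg.n_perm, seed=cfg.seed + 4)
        report["ibd"] = {"mantel_r": ibd.r, "p_value": ibd.p_value}
        if "pcoa" in state:
            axis1 = {sid: c for sid, c in zip(state["pcoa"].sample_ids,
                                              state["pcoa"].coordinates[:, 0])}
            ax = [axis1[i] for i in ids]
            r_lon, p_lon = sp.axis_gradient_correlation(
                ax, coords.loc[ids, "longitude"].to_numpy())
            r_lat, p_lat = sp.axis_gradient_correlation(
                ax, coords.loc[ids, "latitude"].to_numpy())
            report["gradient"] = {"r_longitude": r_lon, "p_longitude": p_lon,
                                  "r_latitude": r_lat, "p_latitude": p_lat}
        climate = pp.climate()
        clim_ids = [i for i in ids if i in climate.index]
        if len(clim_ids) >= 4:
            dclim, pct = sp.climate_pc1_distance(climate.loc[clim_ids])
            dgeo2 = geo.submatrix(clim_ids)
            resp = lin.submatrix(clim_ids)
            fit = sp.mrm(resp, {"geographic": dgeo2, "climatic": dclim},
                         n_perm=cfg.n_perm, seed=cfg.seed + 5)
            report["mrm"] = {"r_squared": fit.r_squared,
                             "p_geographic": float(fit.p_values["geographic"]),
                             "p_climatic": float(fit.p_values["climatic"]),
                             "climate_pc1_pct": pct}

    report["wall_time_s"] = round(time.time() - t0, 3)
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
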