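"""End-to-end pipeline: structure -> sites -> PB -> titration -> Em profile
-> decomposition -> field map -> hopping kinetics, driven by one config.

The config is a plain YAML document (see :func:`validate_config`); every
stochastic stage requires an explicit seed, all outputs are CSV/PQR/OpenDX
text files, and a plain-text manifest records seeds, conditions, versions
and per-stage wall time so any run can be reproduced.
"""

from __future__ import annotations

import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .field import FieldBox, solve_field
from .hopping import lambda_sweep
from .pb import PBParams
from .redox import em_profile, profile_table
from .structure import define_sites, read_pdb, read_pqr, write_pqr, \
    edge_to_edge_distance
from .synth import (make_born_ion, make_coupled_redox_proton,
                    make_kirkwood_sphere, make_layered_protein,
                    make_site_cluster)
from .titration import (TitrationConditions, compute_site_energetics,
                        enumerate_exact, mc_titrate)

STAGES = ("structure", "energetics", "titrate", "em", "field", "hops")

_FIXTURES = {
    "born_ion": make_born_ion,
    "kirkwood_sphere": make_kirkwood_sphere,
    "layered_protein": make_layered_protein,
    "site_cluster": make_site_cluster,
    "coupled_redox_proton": make_coupled_redox_proton,
}


class ConfigError(ValueError):
    """Invalid run configuration."""


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def validate_config(config: dict) -> dict:
    """Validate a run config before any computation.

    Raises :class:`ConfigError` on missing seeds for stochastic stages or
    unknown fixture kinds.
    """
    cfg = dict(config)
    if "fixture" not in cfg and "input" not in cfg:
        raise ConfigError("config needs a 'fixture' or 'input' section")
    if "fixture" in cfg:
        kind = cfg["fixture"].get("kind")
        if kind not in _FIXTURES:
            raise ConfigError(f"unknown fixture kind {kind!r}")
        if kind not in ("born_ion", "kirkwood_sphere") \
                and "seed" not in cfg["fixture"]:
            raise ConfigError(f"fixture {kind!r} is randomized and needs "
                              "an explicit seed")
    tit = cfg.get("titration", {})
    if tit.get("backend", "exact") == "mc" and "seed" not in tit:
        raise ConfigError("Monte Carlo titration needs an explicit seed")
    return cfg


def _build_structure(cfg, seed_override=None):
    if "fixture" in cfg:
        spec = dict(cfg["fixture"])
        kind = spec.pop("kind")
        if seed_override is not None and "seed" in spec:
            spec["seed"] = seed_override
        out = _FIXTURES[kind](**spec)
        if isinstance(out, tuple):
            return out
        return out, []
    inp = cfg["input"]
    if "pqr" in inp:
        st = read_pqr(inp["pqr"])
    else:
        st = read_pdb(inp["pdb"], retain_waters=inp.get("retain_waters", ()),
                      zero_charge_fallback=inp.get("zero_charge_fallback",
                                                   False))
    if inp.get("interfaces"):
        st.interfaces = tuple(inp["interfaces"])
    sites = define_sites(st, redox_residues=inp.get("redox_residues", ()),
                         fixed_states=inp.get("fixed_states"))
    return st, sites


def run_pipeline(config: dict, out_dir, stages=None, resume: bool = False,
                 seed_override: int | None = None) -> dict:
    """Execute the pipeline and return the manifest dict.

    ``stages`` restricts execution (dependencies are resolved upstream of
    the request); with ``resume`` stages whose outputs already exist are
    skipped.  A failing stage stops the run after writing the manifest with
    the failure recorded, leaving completed outputs in place.
    """
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(stages or STAGES)
    manifest = {"pbem_version": __version__,
                "config": yaml.safe_dump(cfg, sort_keys=True).strip(),
                "seed_override": seed_override}
    cond_cfg = cfg.get("conditions", {})
    cond = TitrationConditions(
        pH=cond_cfg.get("pH", 7.0),
        temperature=cond_cfg.get("temperature", 300.0),
        ionic_strength=cond_cfg.get("ionic_strength", 0.1))
    params = PBParams(ionic_strength=cond.ionic_strength,
                      temperature=cond.temperature,
                      **cfg.get("pb", {}))
    state = {}

    def stage_done(name):
        return (out / f".{name}.done").exists()

    def mark_done(name):
        (out / f".{name}.done").write_text("done\n")

    try:
        t0 = time.time()
        st, sites = _build_structure(cfg, seed_override)
        state["structure"], state["sites"] = st, sites
        if "structure" in stages and not (resume and stage_done("structure")):
            write_pqr(st, out / "structure.pqr")
            mark_done("structure")
        manifest["t_structure_s"] = round(time.time() - t0, 2)
        manifest["n_atoms"] = st.n_atoms
        manifest["n_sites"] = len(sites)

        if "energetics" in stages and not sites \
                and np.any(st.charges != 0):
            # analytic-oracle fixtures (Born ion, Kirkwood sphere): report
            # the reaction-field (solvation) energy of the charge set
            from .pb import reaction_field_energy
            t0 = time.time()
            src = np.flatnonzero(st.charges != 0)
            e = reaction_field_energy(st.positions[src], st.charges[src],
                                      st.positions, st.radii, params)
            pd.DataFrame([{"reaction_field_kcal_mol": e}]).to_csv(
                out / "solvation.csv", index=False)
            manifest["t_energetics_s"] = round(time.time() - t0, 2)

        if any(s in stages for s in ("energetics", "titrate", "em", "hops")) \
                and sites:
            t0 = time.time()
            eng = compute_site_energetics(st, sites, params)
            state["energetics"] = eng
            rows = []
            for i, sid in enumerate(eng.site_ids):
                for k in range(1, eng.n_states[i]):
                    tag, value = eng.state_kinds[i][k]
                    rows.append({"site_id": sid, "state": k,
                                 "transition": tag, "intrinsic": value})
            pd.DataFrame(rows).to_csv(out / "intrinsic.csv", index=False)
            np.savetxt(out / "interaction_w.csv",
                       eng.W.max(axis=(2, 3)), delimiter=",")
            manifest["t_energetics_s"] = round(time.time() - t0, 2)

        if "titrate" in stages and sites:
            t0 = time.time()
            tit = cfg.get("titration", {})
            backend = tit.get("backend", "exact")
            if backend == "mc":
                pops = mc_titrate(state["energetics"], cond,
                                  n_sweeps=tit.get("sweeps", 100_000),
                                  seed=(seed_override
                                        if seed_override is not None
                                        else tit["seed"]))
            else:
                pops = enumerate_exact(state["energetics"], cond)
            state["populations"] = pops
            rows = []
            for i, sid in enumerate(pops.site_ids):
                for k, lab in enumerate(pops.state_labels[i]):
                    rows.append({"site_id": sid, "state": lab,
                                 "occupancy": pops.occupancies[i, k],
                                 "mc_error": pops.mc_error[i, k]})
            pd.DataFrame(rows).to_csv(out / "populations.csv", index=False)
            manifest["t_titrate_s"] = round(time.time() - t0, 2)
            manifest["titration_backend"] = backend

        if "em" in stages and any(s.kind == "redox" for s in sites):
            t0 = time.time()
            records = em_profile(st, sites, params, cond,
                                 energetics=state.get("energetics"))
            state["em_records"] = records
            profile_table(records).to_csv(out / "em_profile.csv",
                                          index=False)
            contrib = []
            for r in records:
                for res, mv in r.per_residue_mv.items():
                    contrib.append({"site_id": r.site_id, "residue": res,
                                    "contribution_mv": mv})
            pd.DataFrame(contrib).to_csv(out / "per_residue.csv",
                                         index=False)
            manifest["t_em_s"] = round(time.time() - t0, 2)

        if "field" in stages and cfg.get("field", {}).get("enabled", False):
            t0 = time.time()
            fcfg = cfg["field"]
            box = FieldBox(box_size=fcfg.get("box_size", 120.0),
                           n_nodes=fcfg.get("n_nodes", 76),
                           membrane_z=(tuple(st.interfaces)
                                       if fcfg.get("membrane")
                                       and st.interfaces else None))
            fmap = solve_field(st, box)
            state["field"] = fmap
            fmap.potential.write_dx(out / "field.dx")
            fmap.slice_z(0.0).to_csv(out / "field_slice_z0.csv",
                                     index=False)
            manifest["t_field_s"] = round(time.time() - t0, 2)

        if "hops" in stages and cfg.get("chain"):
            t0 = time.time()
            ccfg = cfg["chain"]
            em_mv = {r.site_id: r.em_mv
                     for r in state.get("em_records", [])}
            em_mv.update(ccfg.get("em_mv", {}))
            residues = list(ccfg["residues"])
            if "distances" in ccfg:
                dists = list(ccfg["distances"])
            else:
                dists = [edge_to_edge_distance(
                    st, tuple(ccfg["members"][a]),
                    tuple(ccfg["members"][b]))
                    for a, b in zip(residues[:-1], residues[1:])]
            ck = lambda_sweep(residues, em_mv, dists,
                              lambda_range=tuple(
                                  ccfg.get("lambda_range", (0.6, 0.8))))
            state["chain"] = ck
            ck.table().to_csv(out / "hops.csv", index=False)
            pd.DataFrame({"lambda_ev": ck.lambdas,
                          "mfpt_ns": ck.mfpt_ns}).to_csv(
                out / "mfpt.csv", index=False)
            manifest["t_hops_s"] = round(time.time() - t0, 2)

        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        _write_manifest(manifest, out)
        raise

    _write_manifest(manifest, out)
    state["manifest"] = manifest
    return state


def _write_manifest(manifest, out: Path):
    with open(out / "manifest.txt", "w") as fh:
        for k, v in manifest.items():
            if k == "config":
                fh.write("config_begin\n" + v + "\nconfig_end\n")
            else:
                fh.write(f"{k} = {v}\n")
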