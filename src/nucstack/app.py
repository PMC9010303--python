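"""Command-line interface.

Thin dispatch over the library: generate synthetic structures, analyze
stacks and fibers, report contacts, and quantify gradient profiles.
Every output directory receives a ``run_metadata.json`` echoing the
tool version, the full configuration, and the geometric conventions in
force (bp per SHL, contact cutoff, mid-frame step definition), so any
output is reproducible from its metadata block alone.  All randomness
flows from the single ``--seed`` option.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path

import click
import numpy as np

from . import __version__
from .contacts import (
    DEFAULT_CUTOFF,
    STRONG_OCCUPANCY_THRESHOLD,
    classify_bridge,
    contact_occupancy,
    find_contacts,
    map_contacts_to_shl,
)
from .errors import NucstackError
from .fiber import classify_start_number, fiber_helix_fit, fiber_steps, order_nucleosomes
from .frames import BP_PER_SHL, pair_base_steps
from .gradient import (
    compare_profiles,
    interpolate_profile,
    normalize_profile,
    profile_centroid,
    read_profile_csv,
)
from .stacking import align_ensemble, ensemble_step_stats, sampling_cloud
from .structio import (
    assign_roles,
    load_role_map,
    read_structure,
    read_trajectory,
    write_records,
)
from .synth import (
    DispersionSpec,
    FiberSpec,
    NucleosomeSpec,
    StackSpec,
    build_fiber,
    build_nucleosome,
    build_stack,
    dispersion_preset,
    fiber_preset,
    nucleosome_preset,
    sample_ensemble,
    write_fixture,
)

CONVENTIONS = {
    "bp_per_shl": BP_PER_SHL,
    "default_contact_cutoff_A": DEFAULT_CUTOFF,
    "strong_occupancy_threshold": STRONG_OCCUPANCY_THRESHOLD,
    "step_convention": "mid-frame (quaternion midpoint); rise along mid z; "
                       "twist signed right-handed about mid z; angles degrees",
}


def _write_metadata(out_dir: Path, config: dict) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {"tool": "nucstack", "version": __version__,
               "config": config, "conventions": CONVENTIONS}
    (out_dir / "run_metadata.json").write_text(json.dumps(payload, indent=1))


def _load_complex(model: str, roles: str):
    return assign_roles(read_structure(model), load_role_map(roles))


@click.group()
@click.version_option(__version__)
def main() -> None:
    """Nucleosome stacking and chromatin-fiber geometry toolkit."""


@main.command("synth")
@click.argument("kind", type=click.Choice(["nucleosome", "stack", "fiber", "ensemble"]))
@click.option("--preset", default=None, help="named preset for the chosen kind")
@click.option("--seed", default=0, type=int, show_default=True)
@click.option("--n-frames", default=100, type=int, show_default=True,
              help="frames for ensemble generation")
@click.option("--out", required=True, type=click.Path(), help="output model path")
def synth_cmd(kind: str, preset: str | None, seed: int, n_frames: int,
              out: str) -> None:
    """Generate a synthetic structure or ensemble with its roles sidecar."""
    out_path = Path(out)
    if kind == "nucleosome":
        obj = build_nucleosome(nucleosome_preset(preset) if preset
                               else NucleosomeSpec())
    elif kind == "stack":
        obj = build_stack(StackSpec())
    elif kind == "fiber":
        obj = build_fiber(fiber_preset(preset) if preset else FiberSpec())
    else:
        base = build_stack(StackSpec())
        disp = (dispersion_preset(preset, n_frames, seed) if preset
                else DispersionSpec(n_frames, seed, sigma_rise=1.0,
                                    sigma_shift=1.0, sigma_tilt=3.0,
                                    sigma_twist=5.0))
        obj = sample_ensemble(base, disp)
    write_fixture(obj, out_path)
    _write_metadata(out_path.parent, {"subcommand": f"synth {kind}",
                                      "preset": preset, "seed": seed,
                                      "n_frames": n_frames, "out": str(out)})
    click.echo(f"wrote {out_path} (+ roles sidecar)")


@main.command("analyze-stack")
@click.option("--model", required=True, type=click.Path(exists=True))
@click.option("--roles", required=True, type=click.Path(exists=True))
@click.option("--trajectory", default=None, type=click.Path(exists=True))
@click.option("--ref-nuc", required=True, help="reference nucleosome id")
@click.option("--mobile-nuc", required=True, help="mobile nucleosome id")
@click.option("--out", required=True, type=click.Path(), help="steps CSV")
@click.option("--cloud", default=None, type=click.Path(), help="sampling-cloud CSV")
def analyze_stack_cmd(model: str, roles: str, trajectory: str | None,
                      ref_nuc: str, mobile_nuc: str, out: str,
                      cloud: str | None) -> None:
    """Inter-nucleosome step parameters (and sampling cloud) of a stack."""
    role_map = load_role_map(roles)
    if trajectory:
        ens = align_ensemble(read_trajectory(trajectory, role_map), ref_nuc)
    else:
        complex_ = _load_complex(model, roles)
        from .structio import TrajectoryEnsemble
        ens = TrajectoryEnsemble(complex_, complex_.structure.coords,
                                 aligned_on=ref_nuc)
    series, summary = ensemble_step_stats(ens, ref_nuc, mobile_nuc)
    write_records(series, out)
    if cloud:
        pc = sampling_cloud(ens, mobile_nuc)
        rows = [{"frame": i,
                 "dyad_x": pc.dyad_points[i, 0], "dyad_y": pc.dyad_points[i, 1],
                 "dyad_z": pc.dyad_points[i, 2],
                 "anti_x": pc.anti_dyad_points[i, 0],
                 "anti_y": pc.anti_dyad_points[i, 1],
                 "anti_z": pc.anti_dyad_points[i, 2]}
                for i in range(pc.frame_count)]
        write_records(rows, cloud)
        click.echo(f"dyad cloud RMS {pc.dyad_rms:.3f} A, "
                   f"anti-dyad RMS {pc.anti_dyad_rms:.3f} A")
    _write_metadata(Path(out).parent, {
        "subcommand": "analyze-stack", "model": model, "roles": roles,
        "trajectory": trajectory, "ref_nuc": ref_nuc,
        "mobile_nuc": mobile_nuc, "out": out, "cloud": cloud})
    click.echo(summary.to_string())


@main.command("analyze-fiber")
@click.option("--model", required=True, type=click.Path(exists=True))
@click.option("--roles", required=True, type=click.Path(exists=True))
@click.option("--out", required=True, type=click.Path(), help="fiber JSON")
@click.option("--steps", default=None, type=click.Path(), help="step CSV")
def analyze_fiber_cmd(model: str, roles: str, out: str,
                      steps: str | None) -> None:
    """Fiber helical parameters and start-number classification."""
    complex_ = _load_complex(model, roles)
    ordered = order_nucleosomes(complex_)
    s1, s2 = fiber_steps(ordered)
    cls = classify_start_number(s1, s2)
    geom = fiber_helix_fit(ordered)
    payload = {
        "n_ordered": geom.n_ordered,
        "rise_per_nucleosome_A": geom.rise_per_nucleosome,
        "twist_per_nucleosome_deg": geom.twist_per_nucleosome,
        "start_number": cls.start_number,
        "start_status": cls.status,
        "stacked_pair_distance_A": geom.stacked_pair_distance,
        "stacked_pair_angle_deg": geom.stacked_pair_angle,
        "axis_direction": geom.axis_direction.tolist(),
        "definition": "stacked pair = (n, n+2); distance between frame "
                      "origins, angle between superhelical axes",
    }
    Path(out).write_text(json.dumps(payload, indent=1))
    if steps:
        rows = []
        for offset, serie in ((1, s1), (2, s2)):
            for i, st in enumerate(serie):
                rows.append({"offset": offset, "step": i, "rise": st.rise,
                             "shift_x": st.shift_x, "shift_y": st.shift_y,
                             "tilt": st.tilt, "twist": st.twist,
                             "center_distance": st.center_distance})
        write_records(rows, steps)
    _write_metadata(Path(out).parent, {
        "subcommand": "analyze-fiber", "model": model, "roles": roles,
        "out": out, "steps": steps})
    click.echo(json.dumps(payload, indent=1))


@main.command("contacts")
@click.option("--model", required=True, type=click.Path(exists=True))
@click.option("--roles", required=True, type=click.Path(exists=True))
@click.option("--cutoff", default=DEFAULT_CUTOFF, type=float, show_default=True)
@click.option("--trajectory", default=None, type=click.Path(exists=True))
@click.option("--occupancy-threshold", default=STRONG_OCCUPANCY_THRESHOLD,
              type=float, show_default=True)
@click.option("--out", required=True, type=click.Path(), help="contacts CSV")
@click.option("--shl-map", default=None, type=click.Path(), help="SHL-bin CSV")
def contacts_cmd(model: str, roles: str, cutoff: float, trajectory: str | None,
                 occupancy_threshold: float, out: str,
                 shl_map: str | None) -> None:
    """Factor-nucleosome contacts, bridge classes and SHL mapping."""
    role_map = load_role_map(roles)
    complex_ = _load_complex(model, roles)
    records = find_contacts(complex_, cutoff)
    write_records(records, out)
    if trajectory:
        ens = read_trajectory(trajectory, role_map)
        occ = contact_occupancy(ens, cutoff, strong_threshold=occupancy_threshold)
        write_records(occ, str(Path(out).with_suffix(".occupancy.csv")))
    if shl_map:
        rows = []
        for factor in complex_.factors:
            bridge = classify_bridge(records, factor.factor_id)
            for nb in bridge.neighbor_nucleosome_ids:
                series = pair_base_steps(complex_, nb)
                smap = map_contacts_to_shl(
                    [c for c in records if c.factor_id == factor.factor_id],
                    series)
                if smap.empty:
                    continue
                for b, count in smap.bin_counts.items():
                    rows.append({"factor_id": factor.factor_id,
                                 "neighbor": nb, "shl_bin_low": b,
                                 "shl_bin_high": b + 1, "contacts": count,
                                 "span_min": smap.span[0],
                                 "span_max": smap.span[1]})
        if rows:
            write_records(rows, shl_map)
    _write_metadata(Path(out).parent, {
        "subcommand": "contacts", "model": model, "roles": roles,
        "cutoff": cutoff, "trajectory": trajectory,
        "occupancy_threshold": occupancy_threshold, "out": out,
        "shl_map": shl_map})
    click.echo(f"{len(records)} contacts at cutoff {cutoff} A")


@main.command("gradient")
@click.option("--csv", "csv_path", required=True, type=click.Path(exists=True))
@click.option("--condition", default=None)
@click.option("--normalize/--no-normalize", default=True, show_default=True)
@click.option("--interpolate", default=0, type=int,
              help="points per fraction for the Akima curve (0 = skip)")
@click.option("--compare", default=None, type=click.Path(exists=True),
              help="second profile CSV; report centroid shift (first - second)")
@click.option("--compare-condition", default=None)
@click.option("--out", required=True, type=click.Path(), help="report JSON")
def gradient_cmd(csv_path: str, condition: str | None, normalize: bool,
                 interpolate: int, compare: str | None,
                 compare_condition: str | None, out: str) -> None:
    """Quantify (and compare) gradient fractionation profiles."""
    profile = read_profile_csv(csv_path, condition=condition)
    if normalize:
        profile = normalize_profile(profile)
    report: dict = {"centroid_fraction": profile_centroid(profile),
                    "normalized": profile.normalized}
    if interpolate:
        grid, values = interpolate_profile(profile, interpolate)
        report["curve"] = {"fraction": grid.tolist(),
                           "intensity": np.asarray(values).tolist()}
    if compare:
        other = read_profile_csv(compare, condition=compare_condition)
        if normalize:
            other = normalize_profile(other)
        report["centroid_shift"] = compare_profiles(profile, other)
    Path(out).write_text(json.dumps(report, indent=1))
    _write_metadata(Path(out).parent, {
        "subcommand": "gradient", "csv": csv_path, "condition": condition,
        "normalize": normalize, "interpolate": interpolate,
        "compare": compare, "compare_condition": compare_condition,
        "out": out})
    click.echo(json.dumps({k: v for k, v in report.items() if k != "curve"},
                          indent=1))


def cli() -> None:
    """Entry point: run the CLI, mapping package errors to exit code 2."""
    try:
        main(standalone_mode=True)
    except NucstackError as exc:
        click.echo(f"error: {exc}", err=True)
        sys.exit(2)


if __name__ == "__main__":
    cli()
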