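"""End-to-end synthetic study: generation, every analysis stage, one report.

``run_study`` wires the whole chain together: generate microclimate for each
configured site, run the irradiance correction/projection and site
summaries, simulate calibrated bench-drying experiments and estimate g_min
per site and exposure temperature, fit the exponential temperature
response, build and analyse Raman cuticle cubes, generate thickness
datasets and run the statistical battery.  All randomness is routed through
named seeds derived from one master seed, so the JSON report is fully
reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import conductance as cond
from . import microclimate as mc
from . import raman
from . import solar
from . import stats as st
from . import synthetic as syn
from . import temp_response as tr

__all__ = ["StudyConfig", "StageError", "run_study", "DEFAULT_CONFIG"]

logger = logging.getLogger("cuticula")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage tag."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"[stage:{stage}] {original}")
        self.stage = stage
        self.original = original


@dataclass
class StudyConfig:
    """Configuration of the synthetic study."""

    scenarios: tuple[syn.SiteScenario, ...] = (syn.N_SITE, syn.S_SITE)
    drying_temperatures: tuple[float, ...] = (25.0, 38.0, 43.0)
    drying_replicates: int = 20
    microclimate_days: int = 10
    microclimate_step_minutes: int = 10
    microclimate_start: str = "2023-06-01"
    thickness_n_per_cell: int = 40
    raman_layers: dict | None = None  # site -> list of (um, label, conc)
    raman_noise_sd: float = 0.02
    master_seed: int = 12345
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if any(t <= 0 for t in self.drying_temperatures):
            raise ValueError("drying temperatures must be positive")
        if self.drying_replicates < 3:
            raise ValueError("need at least 3 drying replicates per cell")


DEFAULT_CONFIG = StudyConfig()


def _default_raman_layers(site: str) -> list[tuple[float, str, float]]:
    # outer aromatic/flavonoid-rich layer thicker on the north slope,
    # inner cutin-rich layer thicker on the southeast slope
    if site == "N":
        return [(7.5, "flavonoids", 1.0), (3.5, "cutin", 1.0)]
    return [(3.5, "flavonoids", 1.0), (12.0, "cutin", 1.0)]


def _seed_for(master: int, label: str) -> int:
    """Stable named sub-seed below 2**31."""
    h = 1469598103934665603  # FNV-1a
    for b in f"{master}:{label}".encode():
        h = ((h ^ b) * 1099511628211) % 2**64
    return h % (2**31 - 1)


def gmin_cell_estimates(
    scenario: syn.SiteScenario,
    temperature: float,
    n_replicates: int,
    seed: int,
    antithetic: bool = True,
    **drying_overrides,
) -> tuple[np.ndarray, int]:
    """Estimate g_min for ``n_replicates`` simulated twigs of one cell.

    With ``antithetic`` (default), per-twig true conductances are drawn in
    antithetic pairs (z, -z) around the calibration mean, a standard
    variance-reduction device that makes the sample mean of the drawn
    truths match the calibration mean exactly for even ``n_replicates``.
    Returns the per-twig estimates and the number of unusable records
    (no detectable plateau) that were skipped.
    """
    rng = np.random.default_rng(seed)
    mean, sd = scenario.gmin_calibration[temperature]
    estimates = []
    failures = 0
    z_prev = 0.0
    for r in range(n_replicates):
        if antithetic:
            z_prev = float(rng.standard_normal()) if r % 2 == 0 else -z_prev
            drying_overrides["true_gmin"] = max(mean + sd * z_prev, 0.05)
        params = syn.drying_params_from_calibration(
            scenario, temperature, rng, **drying_overrides
        )
        exp = syn.generate_drying_experiment(
            params, sample_id=f"{scenario.name}-{temperature:g}C-{r:03d}"
        )
        try:
            estimates.append(cond.estimate_gmin(exp).gmin)
        except cond.PlateauNotFoundError:
            failures += 1
    return np.asarray(estimates), failures


def run_study(config: StudyConfig = DEFAULT_CONFIG) -> dict:
    """Run every stage on synthetic data; returns the study report dict.

    When ``config.output_dir`` is set, per-stage artifacts (microclimate
    CSVs, the JSON report) are written there.
    """
    report: dict = {"config": {"master_seed": config.master_seed,
                               "drying_replicates": config.drying_replicates,
                               "drying_temperatures": list(config.drying_temperatures),
                               "thickness_n_per_cell": config.thickness_n_per_cell},
                    "sites": {}}
    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    gmin_by_site: dict[str, dict[float, np.ndarray]] = {}

    for scenario in config.scenarios:
        site = scenario.name
        site_report: dict = {}
        logger.info("site %s: generating microclimate", site)

        # --- microclimate + irradiance ---------------------------------
        try:
            start = np.datetime64(config.microclimate_start)
            end = start + np.timedelta64(config.microclimate_days, "D")
            series = syn.generate_microclimate(
                scenario,
                str(start),
                str(end),
                step_minutes=config.microclimate_step_minutes,
                seed=_seed_for(config.master_seed, f"microclimate:{site}"),
            )
            if out_dir:
                syn.write_microclimate_csv(series, out_dir / f"microclimate_{site}.csv")
        except Exception as e:
            raise StageError(f"microclimate:{site}", e) from e

        try:
            eff = solar.effective_ppfd_series(
                series.timestamps,
                series.ppfd_horizontal,
                scenario.latitude,
                scenario.longitude,
                solar.SurfaceNormal(
                    elevation=scenario.normal_elevation,
                    azimuth=scenario.normal_azimuth,
                ),
                utc_offset_hours=scenario.utc_offset_hours,
            )
            daily_max_eff = solar.daily_maxima(eff.to_frame(), "ppfd_effective")
            daily_max_meas = solar.daily_maxima(eff.to_frame(), "ppfd_measured")
            site_report["irradiance"] = {
                "mean_daily_max_effective_ppfd": float(daily_max_eff.mean()),
                "mean_daily_max_measured_ppfd": float(daily_max_meas.mean()),
                "absolute_max_effective_ppfd": float(daily_max_eff.max()),
            }
        except Exception as e:
            raise StageError(f"irradiance:{site}", e) from e

        try:
            summary = mc.summarize_site(series)
            site_report["microclimate_summary"] = summary.to_dict()
        except Exception as e:
            raise StageError(f"summary:{site}", e) from e

        # --- g_min per exposure temperature ----------------------------
        try:
            cells = {}
            gmin_by_site[site] = {}
            for temp in config.drying_temperatures:
                if temp not in scenario.gmin_calibration:
                    continue
                est, failures = gmin_cell_estimates(
                    scenario,
                    temp,
                    config.drying_replicates,
                    _seed_for(config.master_seed, f"gmin:{site}:{temp:g}"),
                )
                gmin_by_site[site][temp] = est
                mean, sd = scenario.gmin_calibration[temp]
                cells[f"{temp:g}"] = {
                    "mean_gmin": float(est.mean()),
                    "sd_gmin": float(est.std(ddof=1)),
                    "n": int(len(est)),
                    "unusable_records": failures,
                    "calibration_mean": mean,
                }
            site_report["gmin"] = cells
        except Exception as e:
            raise StageError(f"gmin:{site}", e) from e

        # --- temperature response --------------------------------------
        try:
            pts = [
                (t, g)
                for t, arr in sorted(gmin_by_site[site].items())
                for g in arr
            ]
            if len({t for t, _ in pts}) >= 3:
                model = tr.fit_temperature_response(pts)
                site_report["temperature_response"] = {
                    "gmin0": model.gmin0,
                    "A": model.A,
                    "R0": model.R0,
                    "residual_sse": model.residual_sse,
                    "n_points": model.n_points,
                }
        except Exception as e:
            raise StageError(f"temp_response:{site}", e) from e

        # --- Kruskal-Wallis across temperatures within the site --------
        try:
            if len(gmin_by_site[site]) >= 2:
                kw = st.kruskal_wallis(
                    {f"{t:g}C": v for t, v in gmin_by_site[site].items()}
                )
                site_report["gmin_kruskal_wallis"] = {
                    "H": kw.statistic,
                    "p_value": kw.p_value,
                    "letters": kw.details["letters"],
                }
        except Exception as e:
            raise StageError(f"gmin_stats:{site}", e) from e

        # --- Raman cube ------------------------------------------------
        try:
            layers = (config.raman_layers or {}).get(site) or _default_raman_layers(site)
            cube = syn.generate_raman_cube(
                layers,
                noise_sd=config.raman_noise_sd,
                baseline_amplitude=0.1,
                cosmic_ray_rate=0.02,
                seed=_seed_for(config.master_seed, f"raman:{site}"),
            )
            cube = raman.crop_spectra(cube)
            cube = raman.remove_cosmic_rays(cube)
            cube = raman.baseline_correct(cube)
            band_img = raman.band_integral_image(cube)
            comps = raman.unmix_components(cube, k_select=len(layers))
            layer_stats = []
            for i in range(len(comps.selected)):
                meas = raman.measure_layer_thickness(
                    comps.selected_maps[i], cube.pixel_size, label=f"component_{i}"
                )
                layer_stats.append(
                    {"component": i, "mean_um": meas.mean, "sd_um": meas.sd}
                )
            cuticle_mask = band_img > 0.5 * band_img.max()
            avg = raman.average_spectrum(cube, cuticle_mask)
            matches = raman.assign_bands(cube.wavenumbers, avg)
            site_report["raman"] = {
                "true_layers": [
                    {"thickness_um": th, "label": lb, "concentration": c}
                    for th, lb, c in layers
                ],
                "component_layers": layer_stats,
                "band_assignment": {
                    k: v["fraction_matched"] for k, v in matches.items()
                },
            }
        except Exception as e:
            raise StageError(f"raman:{site}", e) from e

        report["sites"][site] = site_report

    # --- thickness statistics (across sites) ---------------------------
    try:
        cal = {}
        for scenario in config.scenarios:
            for side, (mean, sd) in scenario.thickness_calibration.items():
                cal[(scenario.name, side)] = (mean, sd, config.thickness_n_per_cell)
        if cal:
            ds = syn.generate_thickness_dataset(
                cal, seed=_seed_for(config.master_seed, "thickness")
            )
            report["thickness_summary"] = ds.group_summaries(["site"]).to_dict(
                orient="records"
            )
            if (
                len({s for s, _ in cal}) == 2
                and len({sd for _, sd in cal}) == 2
            ):
                anova = st.two_way_anova_tukey(ds)
                report["thickness_anova"] = {
                    "F_site": anova.details["F_site"],
                    "p_site": anova.details["p_site"],
                    "F_side": anova.details["F_side"],
                    "p_side": anova.details["p_side"],
                    "F_interaction": anova.details["F_interaction"],
                    "p_interaction": anova.details["p_interaction"],
                    "levene_p": anova.details["levene_p"],
                    "shapiro_p": anova.details["shapiro_p"],
                }
    except Exception as e:
        raise StageError("thickness_stats", e) from e

    if out_dir:
        (out_dir / "study_report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True)
        )
    return report
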