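"""End-to-end orchestration: simulate → bin → climate → correlate → manor.

`run_all` drives every stage from a single :class:`RunConfig`, writes all
intermediate and final tables into a run directory together with a config
echo and a log file, and stamps outputs with the config hash and seed for
provenance.  Any stage failure aborts with the stage name while keeping
the partial outputs already written.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as bcio
from .association import run_association_suite, summary_table
from .binning import BinSpec, aggregate_bins
from .climate import bin_proxy, cross_region_correlation, regional_mean_precip, rolling_mean
from .manor import century_summary, normality_report, stability_suite
from .synthetic import SynthConfig, gen_climate, gen_contexts, gen_manor, gen_stations, ground_truth

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Settings for one end-to-end run.

    With ``simulate=True`` (default) all four input tables are generated
    synthetically from ``seed``; otherwise the four paths must point to
    existing delimited-text tables.
    """

    outdir: str = "run_output"
    seed: int = 0
    simulate: bool = True
    arch_path: str | None = None
    varve_path: str | None = None
    cit_path: str | None = None
    manor_path: str | None = None
    stations_path: str | None = None
    # binning
    start_year: int = 100
    end_year: int = 1800
    bin_width: int = 100
    max_span: int = 200
    agg_mode: str = "mean"
    agg_unit: str = "context"
    # climate
    smooth_window: int = 50
    smooth_varve: bool = True
    station_from_year: int | None = None
    # association
    n_perm: int = 10_000
    alternative: str = "two_sided"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def validate_paths(self) -> None:
        if self.simulate:
            return
        for name in ("arch_path", "varve_path", "cit_path", "manor_path"):
            p = getattr(self, name)
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"{name} = {p!r} does not exist")


def run_all(config: RunConfig) -> Path:
    """Run the full pipeline and return the run directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tag = f"{config.config_hash()}_seed{config.seed}"

    handler = logging.FileHandler(outdir / "run.log", mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("buffercrops")
    root.addHandler(handler)
    root.setLevel(config.log_level)
    stage = "setup"
    try:
        with open(outdir / "config_echo.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(
                {"config_hash": tag, **dataclasses.asdict(config)}, fh, sort_keys=False
            )

        stage = "inputs"
        config.validate_paths()
        if config.simulate:
            synth = SynthConfig(seed=config.seed)
            varve, cit = gen_climate(synth)
            contexts = gen_contexts(synth, (varve, cit))
            manors = gen_manor(synth)
            stations = gen_stations(synth)
            bcio.write_arch_table(contexts, outdir / f"arch_contexts_{tag}.csv")
            bcio.write_proxy_series(varve, outdir / f"varve_{tag}.csv")
            bcio.write_proxy_series(cit, outdir / f"cit_{tag}.csv")
            bcio.write_manor_table(manors, outdir / f"manor_{tag}.csv")
            bcio.write_station_table(stations, outdir / f"stations_{tag}.csv")
            bcio.write_results(ground_truth(synth), outdir / f"ground_truth_{tag}.json", "json")
        else:
            contexts = bcio.read_arch_table(config.arch_path)
            varve = bcio.read_proxy_series(config.varve_path, name="varve_thickness")
            cit = bcio.read_proxy_series(config.cit_path, name="cit_temperature")
            manors = bcio.read_manor_table(config.manor_path)
            stations = (
                bcio.read_station_tables(config.stations_path)
                if config.stations_path
                else None
            )

        stage = "bin"
        spec = BinSpec(
            start_year=config.start_year, end_year=config.end_year,
            width=config.bin_width, max_span=config.max_span,
        )
        series = aggregate_bins(contexts, spec, mode=config.agg_mode, unit=config.agg_unit)
        bcio.write_results(series, outdir / f"bin_series_{tag}.csv")

        stage = "climate"
        varve_prepped = (
            rolling_mean(varve, config.smooth_window) if config.smooth_varve else varve
        )
        proxies = [bin_proxy(varve_prepped, spec), bin_proxy(cit, spec)]
        for proxy in proxies:
            bcio.write_results(
                __binned_frame(proxy), outdir / f"binned_{proxy.name}_{tag}.csv"
            )
        if stations:
            pa = regional_mean_precip(stations, "proxy_region")
            pb = regional_mean_precip(stations, "study_region")
            r, n = cross_region_correlation(pa, pb, from_year=config.station_from_year)
            bcio.write_results(
                {"pearson_r": r, "n_overlap": n,
                 "from_year": config.station_from_year},
                outdir / f"station_correlation_{tag}.json", "json",
            )
            logger.info("station cross-region correlation r=%.4f over %d years", r, n)

        stage = "correlate"
        assoc = run_association_suite(
            series, proxies, n_perm=config.n_perm,
            alternative=config.alternative, seed=config.seed,
        )
        bcio.write_results(assoc, outdir / f"associations_{tag}.csv")
        bcio.write_results(summary_table(assoc), outdir / f"association_summary_{tag}.csv")
        bcio.write_results(assoc, outdir / f"associations_{tag}.json", "json")

        stage = "manor"
        summaries = century_summary(manors)
        bcio.write_results(summaries, outdir / f"century_summary_{tag}.csv")
        tests = stability_suite(manors)
        bcio.write_results(tests, outdir / f"stability_tests_{tag}.csv")
        bcio.write_results(tests, outdir / f"stability_tests_{tag}.json", "json")
        bcio.write_results(
            normality_report(manors), outdir / f"normality_report_{tag}.json", "json"
        )
    except Exception as exc:
        logger.error("pipeline failed at stage %r: %s", stage, exc)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
    return outdir


def __binned_frame(proxy):
    import pandas as pd

    return pd.DataFrame(proxy.bins, columns=["bin_start", "mean_value", "n_samples"])
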