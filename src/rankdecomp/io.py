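"""Dataset reading/validation, run configuration and report writing.

The sole tabular input format is CSV with a header row. A run
configuration names the column roles (health, socioeconomic score *or*
precomputed rank deviation, weight, covariates), the health bounds, which
indices and decompositions to compute, the estimator, and the SEM block.
Configurations can be loaded from a YAML file; every option also has a CLI
flag (see :mod:`rankdecomp.cli`).

Reports are written in machine precision to CSV and, for the main tables,
as aligned two-decimal text in the layout of the printed decomposition
tables (a "Total 100.00" row closes every percentage table).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._weights import wmean
from .decomp import (
    decompose_health,
    decompose_rank,
    decompose_simultaneous,
    percentages,
)
from .errors import ConfigError, DataError
from .ranks import HealthVector, fractional_ranks, gc_covariance, gc_product, scale_index
from .regress import CONST, DesignMatrix, add_constant, wls_fit
from .sem import SEMSpec, sem_pipeline

__all__ = ["RunConfig", "Dataset", "read_dataset", "run_analysis"]

log = logging.getLogger("rankdecomp")


@dataclass(frozen=True)
class RunConfig:
    """Everything a run needs; exactly one of score_col/deviation_col set."""

    dataset: str
    health_col: str
    score_col: str | None = None
    deviation_col: str | None = None
    weight_col: str | None = None
    covariates: tuple[str, ...] = ()
    bounds: tuple[float, float] | None = (0.0, 1.0)
    indices: tuple[str, ...] = ("GC", "C", "W", "E")
    decompositions: tuple[str, ...] = ("I", "II", "III")
    estimator: str = "ols"  # "ols" or "gmm"
    sem: SEMSpec | None = None
    alpha: float = 0.05
    robust: str = "HC1"
    include_rank_in_health_eq: bool = False
    center_square_of: str | None = None  # derive (col - wmean)^2 column
    outdir: str = "rankdecomp_out"
    seed: int = 0

    def __post_init__(self):
        if (self.score_col is None) == (self.deviation_col is None):
            raise ConfigError(
                "exactly one of score_col / deviation_col must be set"
            )
        if self.estimator not in ("ols", "gmm"):
            raise ConfigError(f"unknown estimator {self.estimator!r}")
        if self.robust not in ("HC0", "HC1"):
            raise ConfigError(f"unknown robust variant {self.robust!r}")
        if self.estimator == "gmm" and self.sem is None:
            raise ConfigError("estimator 'gmm' requires a sem block")
        object.__setattr__(self, "covariates", tuple(self.covariates))
        object.__setattr__(self, "indices", tuple(self.indices))
        object.__setattr__(self, "decompositions", tuple(self.decompositions))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sem_block = raw.pop("sem", None)
        sem = SEMSpec(**sem_block) if sem_block else None
        bounds = raw.pop("bounds", (0.0, 1.0))
        try:
            return cls(
                sem=sem,
                bounds=tuple(bounds) if bounds is not None else None,
                **raw,
            )
        except TypeError as exc:
            raise ConfigError(f"invalid configuration key: {exc}") from exc


@dataclass(frozen=True)
class Dataset:
    """Validated columns ready for analysis."""

    frame: pd.DataFrame
    health_col: str
    rank_source: str  # the score or deviation column name
    rank_is_score: bool
    weight_col: str | None
    covariates: tuple[str, ...]
    n_dropped: int

    @property
    def h(self) -> np.ndarray:
        return self.frame[self.health_col].to_numpy(dtype=float)

    @property
    def weights(self) -> np.ndarray:
        if self.weight_col is None:
            return np.ones(len(self.frame))
        return self.frame[self.weight_col].to_numpy(dtype=float)

    def rank_deviations(self) -> np.ndarray:
        """Fractional rank deviations: computed from the score column, or
        taken as-is from a precomputed deviation column."""
        if self.rank_is_score:
            return fractional_ranks(
                self.frame[self.rank_source].to_numpy(dtype=float), self.weights
            ).d
        return self.frame[self.rank_source].to_numpy(dtype=float)


def read_dataset(path: str | Path, config: RunConfig) -> Dataset:
    """Read and validate the CSV named by the config roles.

    Rows with missing values in any role column are dropped (count
    logged). A derived centered-square column is created on request:
    ``<col>_sq_c = (col - weighted mean)^2``.
    """
    try:
        df = pd.read_csv(path)
    except FileNotFoundError as exc:
        raise DataError(f"dataset file not found: {path}") from exc

    rank_source = config.score_col or config.deviation_col
    roles = [config.health_col, rank_source]
    if config.weight_col:
        roles.append(config.weight_col)
    roles += [c for c in config.covariates if not c.endswith("_sq_c")]
    missing = [c for c in roles if c not in df.columns]
    if missing:
        raise DataError(
            f"dataset lacks required role column(s): {missing}; "
            f"available: {list(df.columns)}"
        )

    for c in roles:
        if not np.issubdtype(pd.to_numeric(df[c], errors="coerce").dtype, np.number):
            raise DataError(f"column {c!r} is not numeric")
        df[c] = pd.to_numeric(df[c], errors="coerce")

    before = len(df)
    df = df.dropna(subset=roles).reset_index(drop=True)
    n_dropped = before - len(df)
    if n_dropped:
        log.info("dropped %d row(s) with missing values", n_dropped)
    if len(df) < 2:
        raise DataError("fewer than 2 complete rows after validation")

    if config.weight_col is not None:
        w = df[config.weight_col].to_numpy(dtype=float)
        if np.any(w <= 0):
            raise DataError("nonpositive sample weights found")
    else:
        w = np.ones(len(df))

    if config.center_square_of is not None:
        base = config.center_square_of
        if base not in df.columns:
            raise DataError(f"cannot derive centered square: no column {base!r}")
        df[f"{base}_sq_c"] = (df[base] - wmean(df[base].to_numpy(float), w)) ** 2

    return Dataset(
        frame=df,
        health_col=config.health_col,
        rank_source=rank_source,
        rank_is_score=config.score_col is not None,
        weight_col=config.weight_col,
        covariates=config.covariates,
        n_dropped=n_dropped,
    )


def _fmt_pct_table(result) -> str:
    lines = [f"{'variable':<28}{'level':>14}{'%':>10}"]
    have_pct = result.percentages is not None
    for name, val in result.terms.items():
        pct = f"{result.percentages[name]:10.2f}" if have_pct else f"{'—':>10}"
        lines.append(f"{name:<28}{val:14.6f}{pct}")
    pct = f"{result.residual_pct:10.2f}" if have_pct else f"{'—':>10}"
    lines.append(f"{'Residual':<28}{result.residual:14.6f}{pct}")
    if have_pct:
        lines.append(f"{'Total':<28}{result.index_value:14.6f}{100.0:10.2f}")
    else:
        lines.append(f"{'Total':<28}{result.index_value:14.6f}{'—':>10}")
    return "\n".join(lines)


def _decomp_frame(result) -> pd.DataFrame:
    rows = {name: {"level": val} for name, val in result.terms.items()}
    rows["residual"] = {"level": result.residual}
    rows["total"] = {"level": result.index_value}
    out = pd.DataFrame(rows).T
    if result.percentages is not None:
        out["percent"] = list(result.percentages) + [result.residual_pct, 100.0]
    return out


def _header(title: str, result, config: RunConfig) -> str:
    return (
        f"# {title}\n"
        f"# n={result.n} weighted={result.weighted} method={result.method} "
        f"index=GC value={result.index_value:.6g}\n"
    )


def run_analysis(config: RunConfig) -> dict:
    """Compute ranks, indices and the selected decompositions; write the
    report bundle to ``config.outdir`` and return the results in memory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logfile = outdir / "run.log"
    handler = logging.FileHandler(logfile, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    results: dict = {}
    try:
        ds = read_dataset(config.dataset, config)
        if ds.n_dropped:
            log.info("validation dropped %d rows", ds.n_dropped)
        w = ds.weights
        h = ds.h
        d = ds.rank_deviations()

        # --- indices ---
        a, bnd = (config.bounds or (None, None))
        hv = HealthVector(h, a_h=a, b_h=bnd)
        if ds.rank_is_score:
            ranks = fractional_ranks(ds.frame[ds.rank_source].to_numpy(float), w)
            gc = gc_product(hv, ranks)
            gc_cov = gc_covariance(hv, ranks)
        else:
            from ._weights import wcov

            gc_val = 2.0 * wcov(h, d, w)
            from .ranks import IndexValue

            gc = IndexValue("GC", gc_val, len(h), bool(np.ptp(w) > 0))
            gc_cov = gc
        mu_h = wmean(h, w)
        idx_rows = {}
        for kind in config.indices:
            if kind == "GC":
                idx_rows["GC"] = gc.value
            else:
                try:
                    idx_rows[kind] = scale_index(gc, kind, mu_h, a, bnd).value
                except ValueError as exc:
                    log.warning("index %s not computed: %s", kind, exc)
        results["indices"] = idx_rows
        pd.Series(idx_rows, name="value").to_csv(outdir / "indices.csv")
        log.info("GC (product form) = %.6g; (covariance form) = %.6g", gc.value, gc_cov.value)

        # --- regressor matrices ---
        cov_cols = list(config.covariates)
        frame = ds.frame

        if config.estimator == "gmm":
            pipe = sem_pipeline(
                config.sem,
                frame.assign(**{"h": h, "d": d}),
                weights=w,
                alpha=config.alpha,
            )
            results["pipeline"] = pipe
            for label, fit in (
                ("h_equation", pipe.final_fit_h),
                ("d_equation", pipe.final_fit_d),
            ):
                fit.summary_frame().to_csv(outdir / f"regression_{label}.csv")
            for decision in pipe.log:
                log.info("%s", decision)
            named = {
                "I": pipe.decomposition_I,
                "II": pipe.decomposition_II,
                "III": pipe.decomposition_III,
            }
            for kind in config.decompositions:
                res = named[kind]
                results[f"decomposition_{kind}"] = res
                _write_decomposition(outdir, kind, res, config)
            pipe.crosstab.matrix.to_csv(outdir / "crosstab.csv")
            _write_direct_combined(outdir, pipe.direct_combined)
        else:
            X = add_constant(frame[cov_cols].copy())
            if config.include_rank_in_health_eq:
                X["d"] = d
            fit_h = wls_fit(DesignMatrix(pd.Series(h), X, w), robust=config.robust)
            fit_h.summary_frame().to_csv(outdir / "regression_h_equation.csv")
            Xd = add_constant(frame[cov_cols].copy())
            fit_d = wls_fit(DesignMatrix(pd.Series(d), Xd, w), robust=config.robust)
            fit_d.summary_frame().to_csv(outdir / "regression_d_equation.csv")
            if "I" in config.decompositions:
                res = decompose_health(fit_h, d, w)
                results["decomposition_I"] = res
                _write_decomposition(outdir, "I", res, config)
            if "II" in config.decompositions:
                res = decompose_rank(fit_d, h, w)
                results["decomposition_II"] = res
                _write_decomposition(outdir, "II", res, config)
            if "III" in config.decompositions:
                res3, crosstab, dc = decompose_simultaneous(fit_h if not config.include_rank_in_health_eq else wls_fit(DesignMatrix(pd.Series(h), add_constant(frame[cov_cols].copy()), w)), fit_d)
                results["decomposition_III"] = res3
                _write_decomposition(outdir, "III", res3, config)
                crosstab.matrix.to_csv(outdir / "crosstab.csv")
                _write_direct_combined(outdir, dc)
        return results
    finally:
        log.removeHandler(handler)
        handler.close()


def _write_decomposition(outdir: Path, kind: str, result, config: RunConfig) -> None:
    if result.percentages is None:
        log.warning(
            "decomposition (%s): GC within tolerance of zero; percentage "
            "table replaced by levels only",
            kind,
        )
    frame = _decomp_frame(result)
    path = outdir / f"decomposition_{kind}.csv"
    with open(path, "w") as fh:
        fh.write(_header(f"decomposition ({kind})", result, config))
        frame.to_csv(fh)
    (outdir / f"decomposition_{kind}.txt").write_text(
        _header(f"decomposition ({kind})", result, config) + _fmt_pct_table(result) + "\n"
    )


def _write_direct_combined(outdir: Path, dc) -> None:
    with open(outdir / "direct_combined.csv", "w") as fh:
        fh.write("# direct and combined shares of decomposition (III), percent\n")
        dc.direct.rename("direct").to_csv(fh)
        fh.write(f"direct_total,{dc.direct_total}\n")
        dc.combined.to_csv(fh)
        fh.write(f"combined_total,{dc.combined_total}\n")
        fh.write(f"residual,{dc.residual_pct}\n")
        fh.write(f"total,{dc.direct_total + dc.combined_total + dc.residual_pct}\n")
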