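"""Instrumentation-strategy optimization engine.

Pipeline: a design space over the six instrumentation variables (UIV, LIV,
implant density, implant type, thoracic and lumbar rod bends) is sampled
with a U-type uniform design (good-lattice-point construction refined by
seeded swap descent on the centered L2 discrepancy); every sampled strategy
is simulated on the patient geometry; per-descriptor linear regression
surrogates are fitted to the simulated responses; and the corrective
objective composed with the surrogates is minimized — first by a
gradient-based continuous relaxation, then by exhaustive evaluation over
the discrete grid so the reported optimum is a true grid minimum.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize as _scipy_minimize

from .biomech_sim import (
    InstrumentationConfig,
    SimResult,
    StiffnessConfig,
    make_implant_plan,
    run_instrumentation,
)
from .descriptors import DescriptorSet, SegmentDef, unfused_count
from .objective import ObjectiveContext, WeightProfile, phi
from .spine_geometry import SpineModel, SpinePlanError, ValidationError, level_index

__all__ = [
    "DesignSpace",
    "DesignMatrix",
    "ResponseTable",
    "SurrogateModel",
    "OptimalStrategy",
    "ConfigurationError",
    "BatchError",
    "FitError",
    "build_design_space",
    "uniform_design",
    "centered_l2_discrepancy",
    "encode_config",
    "decode_codes",
    "run_batch",
    "fit_surrogate",
    "predict_descriptors",
    "minimize_phi",
    "summarize_strategies",
    "load_published_strategies",
]

log = logging.getLogger(__name__)

_DATA_DIR = Path(__file__).parent / "data"

#: descriptor responses fitted by the surrogate (F is computed exactly)
RESPONSE_FIELDS = (
    "theta_PT", "theta_MT", "theta_TLL", "X_AVT", "theta_TK", "theta_LL",
    "theta_AVR_PT", "theta_AVR_MT", "theta_AVR_TLL",
    "theta_PMC_PT", "theta_PMC_MT", "theta_PMC_TLL",
)
#: responses that are non-negative by definition (clamped when predicted < 0)
_NONNEG_FIELDS = ("theta_PT", "theta_MT", "theta_TLL",
                  "theta_PMC_PT", "theta_PMC_MT", "theta_PMC_TLL")


class ConfigurationError(SpinePlanError):
    """Invalid design-space configuration."""


class BatchError(SpinePlanError):
    """Too many simulation failures in a batch."""


class FitError(SpinePlanError):
    """Surrogate regression failure."""


@dataclass
class DesignSpace:
    """Discrete level sets for the six instrumentation design variables."""

    uiv_levels: tuple[str, ...] = ("T2", "T3", "T4", "T5")
    liv_levels: tuple[str, ...] = ("T11", "T12", "L1", "L2", "L3", "L4")
    density_levels: tuple[str, ...] = ("every", "alternate", "ends_apex")
    type_levels: tuple[str, ...] = ("screw", "hybrid")
    rod_thoracic_levels: tuple[float, ...] = (10.0, 20.0, 30.0)
    rod_lumbar_levels: tuple[float, ...] = (30.0, 45.0, 60.0)

    @property
    def variables(self) -> list[tuple[str, tuple]]:
        return [
            ("uiv", self.uiv_levels),
            ("liv", self.liv_levels),
            ("density", self.density_levels),
            ("implant_type", self.type_levels),
            ("rod_thoracic", self.rod_thoracic_levels),
            ("rod_lumbar", self.rod_lumbar_levels),
        ]

    @property
    def level_counts(self) -> tuple[int, ...]:
        return tuple(len(levels) for _name, levels in self.variables)

    @property
    def cardinality(self) -> int:
        return int(np.prod(self.level_counts))

    def validate(self) -> None:
        for name, levels in self.variables:
            if len(levels) == 0:
                raise ConfigurationError(f"empty level set for {name}")
        feasible = [
            (u, l) for u in self.uiv_levels for l in self.liv_levels
            if level_index(u) < level_index(l)
        ]
        if not feasible:
            raise ConfigurationError("no feasible UIV/LIV pair: empty design space")
        if len(feasible) < len(self.uiv_levels) * len(self.liv_levels):
            raise ConfigurationError(
                "design space contains infeasible UIV/LIV pairs; restrict the "
                "level sets so every combination is feasible")

    def enumerate_codes(self) -> np.ndarray:
        """All grid points as ordinal code rows (cardinality x 6)."""
        ranges = [range(q) for q in self.level_counts]
        return np.array(list(itertools.product(*ranges)), dtype=int)

    def config_from_codes(self, codes) -> InstrumentationConfig:
        return decode_codes(np.asarray(codes, dtype=int), self)


def build_design_space(cfg: dict | None = None) -> DesignSpace:
    """Design space from a configuration mapping (defaults when omitted)."""
    cfg = cfg or {}
    space = DesignSpace(
        uiv_levels=tuple(cfg.get("uiv_levels", DesignSpace.uiv_levels)),
        liv_levels=tuple(cfg.get("liv_levels", DesignSpace.liv_levels)),
        density_levels=tuple(cfg.get("density_levels", DesignSpace.density_levels)),
        type_levels=tuple(cfg.get("type_levels", DesignSpace.type_levels)),
        rod_thoracic_levels=tuple(cfg.get("rod_thoracic_levels",
                                          DesignSpace.rod_thoracic_levels)),
        rod_lumbar_levels=tuple(cfg.get("rod_lumbar_levels",
                                        DesignSpace.rod_lumbar_levels)),
    )
    space.validate()
    return space


# ---------------------------------------------------------------------------
# Encoding
# ---------------------------------------------------------------------------

def decode_codes(codes: np.ndarray, space: DesignSpace) -> InstrumentationConfig:
    """Ordinal code row -> InstrumentationConfig."""
    vals = [levels[int(c)] for (c, (_n, levels)) in zip(codes, space.variables)]
    uiv, liv, density, implant_type, rod_t, rod_l = vals
    return InstrumentationConfig(
        uiv=uiv, liv=liv,
        implant_plan=make_implant_plan(uiv, liv, density, implant_type),
        rod_thoracic_bend=float(rod_t), rod_lumbar_bend=float(rod_l),
    )


def codes_of_config(config: InstrumentationConfig, space: DesignSpace) -> np.ndarray:
    """InstrumentationConfig -> ordinal code row (inverse of decode)."""
    density = _density_of_plan(config)
    implant_type = _type_of_plan(config)
    values = (config.uiv, config.liv, density, implant_type,
              config.rod_thoracic_bend, config.rod_lumbar_bend)
    codes = []
    for val, (name, levels) in zip(values, space.variables):
        try:
            codes.append(levels.index(val))
        except ValueError:
            raise ConfigurationError(
                f"config is off-grid: {name}={val!r} not in {levels}") from None
    return np.array(codes, dtype=int)


def _density_of_plan(config: InstrumentationConfig) -> str:
    for density in ("every", "alternate", "ends_apex"):
        if set(make_implant_plan(config.uiv, config.liv, density, "screw")) \
                == set(config.implant_plan):
            return density
    raise ConfigurationError("implant plan matches no density level")


def _type_of_plan(config: InstrumentationConfig) -> str:
    types = set(config.implant_plan.values())
    return "screw" if types == {"screw"} else "hybrid"


def codes_to_unit(codes: np.ndarray, space: DesignSpace) -> np.ndarray:
    """Ordinal codes -> [-1, 1] per variable (midpoint of odd counts at 0;
    a single-level variable maps to 0)."""
    q = np.array(space.level_counts, dtype=float)
    denom = np.where(q > 1, q - 1.0, 1.0)
    x = 2.0 * np.asarray(codes, dtype=float) / denom - 1.0
    return np.where(q > 1, x, 0.0)


def unit_to_codes(x: np.ndarray, space: DesignSpace) -> np.ndarray:
    q = np.array(space.level_counts, dtype=float)
    codes = np.rint((np.asarray(x, dtype=float) + 1.0) * (q - 1.0) / 2.0)
    return np.clip(codes, 0, q - 1).astype(int)


def encode_config(config: InstrumentationConfig, space: DesignSpace) -> np.ndarray:
    """Numeric predictor vector in [-1, 1]^6 for a grid configuration."""
    return codes_to_unit(codes_of_config(config, space), space)


# ---------------------------------------------------------------------------
# U-type uniform design
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    """n_runs encoded configurations sampled from a design space."""

    codes: np.ndarray            # (n_runs, 6) ordinal codes
    space: DesignSpace
    discrepancy: float

    @property
    def n_runs(self) -> int:
        return len(self.codes)

    def configs(self) -> list[InstrumentationConfig]:
        return [decode_codes(row, self.space) for row in self.codes]

    def encoded(self) -> np.ndarray:
        return codes_to_unit(self.codes, self.space)


def centered_l2_discrepancy(codes: np.ndarray, level_counts) -> float:
    """Centered L2 discrepancy of a U-type design (levels at cell centers)."""
    q = np.asarray(level_counts, dtype=float)
    x = (np.asarray(codes, dtype=float) + 0.5) / q
    n, d = x.shape
    u = np.abs(x - 0.5)
    term1 = (13.0 / 12.0) ** d
    prod1 = np.prod(1.0 + 0.5 * u - 0.5 * u**2, axis=1)
    term2 = 2.0 / n * prod1.sum()
    diff = np.abs(x[:, None, :] - x[None, :, :])
    cross = np.prod(1.0 + 0.5 * u[:, None, :] + 0.5 * u[None, :, :] - 0.5 * diff,
                    axis=2)
    term3 = cross.sum() / n**2
    return float(np.sqrt(max(term1 - term2 + term3, 0.0)))


def _glp_codes(n_runs: int, level_counts, seed: int) -> np.ndarray:
    """Good-lattice-point start: balanced columns from coprime generators."""
    rng = np.random.default_rng(seed)
    gens = [h for h in range(2, 10 * n_runs) if math.gcd(h, n_runs) == 1]
    cols = []
    i = np.arange(n_runs)
    for j, q in enumerate(level_counts):
        h = gens[j]
        k = (i * h) % n_runs
        cols.append((k * q) // n_runs)
    codes = np.column_stack(cols).astype(int)
    # break duplicate rows by balanced in-column swaps, one sweep at a time
    for _ in range(50):
        _vals, inv, counts = np.unique(codes, axis=0, return_inverse=True,
                                       return_counts=True)
        if counts.max() == 1:
            break
        seen: set[int] = set()
        for r1 in range(n_runs):
            grp = int(inv[r1])
            if counts[grp] == 1 or grp not in seen and not seen.add(grp):
                continue  # keep the first occurrence of each duplicate group
            r2 = int(rng.integers(n_runs))
            j = int(rng.integers(codes.shape[1]))
            codes[[r1, r2], j] = codes[[r2, r1], j]
    # exact repair of any stragglers: scan partners/columns for a swap that
    # removes the duplicate without creating a new one
    for _ in range(n_runs):
        dups = _duplicate_row_indices(codes)
        if len(dups) == 0:
            break
        keys = {tuple(row) for row in map(tuple, codes)}
        r1 = int(dups[-1])
        fixed = False
        for r2 in rng.permutation(n_runs):
            if fixed:
                break
            for j in range(codes.shape[1]):
                if codes[r1, j] == codes[r2, j]:
                    continue
                k1 = list(codes[r1]); k2 = list(codes[r2])
                k1[j], k2[j] = codes[r2, j], codes[r1, j]
                if tuple(k1) in keys or tuple(k2) in keys:
                    continue
                codes[r1], codes[r2] = k1, k2
                fixed = True
                break
        if not fixed:
            raise ConfigurationError(
                "could not construct a duplicate-free balanced design")
    return codes


def _duplicate_row_indices(codes: np.ndarray) -> np.ndarray:
    _vals, inv, counts = np.unique(codes, axis=0, return_inverse=True,
                                   return_counts=True)
    return np.where(counts[inv] > 1)[0]


def uniform_design(space: DesignSpace, n_runs: int = 702, seed: int = 0,
                   refine_iters: int = 300) -> DesignMatrix:
    """U-type uniform design over the instrumentation grid.

    Starts from a good-lattice-point construction (level-balanced by
    construction: each level of a q-level variable occupies floor(n/q) or
    ceil(n/q) runs) and improves it by seeded greedy swap descent on the
    centered L2 discrepancy; swaps exchange two rows' codes within one
    column, preserving balance and row distinctness."""
    space.validate()
    if n_runs > space.cardinality:
        raise ConfigurationError(
            f"n_runs={n_runs} exceeds the design-space cardinality "
            f"{space.cardinality}")
    q = space.level_counts
    if n_runs == space.cardinality:
        codes = space.enumerate_codes()
        return DesignMatrix(codes=codes, space=space,
                            discrepancy=centered_l2_discrepancy(codes, q))
    rng = np.random.default_rng(seed)
    codes = _glp_codes(n_runs, q, seed)

    # incremental swap descent: a swap touches two rows only, so the row
    # products entering the discrepancy are patched rather than recomputed
    qf = np.asarray(q, dtype=float)
    n, d = codes.shape

    def _x(c):
        return (np.asarray(c, dtype=float) + 0.5) / qf

    x = _x(codes)
    u = np.abs(x - 0.5)
    prod1 = np.prod(1.0 + 0.5 * u - 0.5 * u**2, axis=1)
    diff = np.abs(x[:, None, :] - x[None, :, :])
    cross = np.prod(1.0 + 0.5 * u[:, None, :] + 0.5 * u[None, :, :] - 0.5 * diff,
                    axis=2)
    term1 = (13.0 / 12.0) ** d

    def _cd2sq():
        return term1 - 2.0 / n * prod1.sum() + cross.sum() / n**2

    best = _cd2sq()
    row_keys = {tuple(row) for row in map(tuple, codes)}
    for _ in range(refine_iters):
        j = int(rng.integers(d))
        r1, r2 = rng.choice(n, size=2, replace=False)
        if codes[r1, j] == codes[r2, j]:
            continue
        k1 = list(codes[r1]); k2 = list(codes[r2])
        k1[j], k2[j] = codes[r2, j], codes[r1, j]
        if tuple(k1) in row_keys or tuple(k2) in row_keys:
            continue
        old_rows = (codes[r1].copy(), codes[r2].copy())
        saved = (x[[r1, r2]].copy(), u[[r1, r2]].copy(), prod1[[r1, r2]].copy(),
                 cross[[r1, r2]].copy(), cross[:, [r1, r2]].copy())
        codes[r1], codes[r2] = k1, k2
        for r in (r1, r2):
            x[r] = _x(codes[r])
            u[r] = np.abs(x[r] - 0.5)
            prod1[r] = np.prod(1.0 + 0.5 * u[r] - 0.5 * u[r]**2)
            row = np.prod(1.0 + 0.5 * u[r][None, :] + 0.5 * u
                          - 0.5 * np.abs(x[r][None, :] - x), axis=1)
            cross[r, :] = row
            cross[:, r] = row
        cd = _cd2sq()
        if cd < best - 1e-15:
            best = cd
            row_keys.discard(tuple(old_rows[0]))
            row_keys.discard(tuple(old_rows[1]))
            row_keys.add(tuple(k1))
            row_keys.add(tuple(k2))
        else:
            codes[r1], codes[r2] = old_rows
            x[[r1, r2]], u[[r1, r2]], prod1[[r1, r2]] = saved[0], saved[1], saved[2]
            cross[[r1, r2]] = saved[3]
            cross[:, [r1, r2]] = saved[4]
    return DesignMatrix(codes=codes, space=space,
                        discrepancy=float(np.sqrt(max(best, 0.0))))


# ---------------------------------------------------------------------------
# Batch simulation
# ---------------------------------------------------------------------------

@dataclass
class ResponseTable:
    """Simulated descriptor responses for a design matrix."""

    table: pd.DataFrame          # codes, encoded x0..x5, responses, F, converged
    space: DesignSpace

    @property
    def n_converged(self) -> int:
        return int(self.table["converged"].sum())

    def converged_rows(self) -> pd.DataFrame:
        return self.table[self.table["converged"]]


def run_batch(spine: SpineModel, dm: DesignMatrix,
              stiffness_cfg: StiffnessConfig | None = None,
              segments: dict[str, SegmentDef] | None = None,
              min_converged_fraction: float = 0.8,
              progress: bool = False) -> ResponseTable:
    """Simulate every configuration of a design matrix.

    Non-convergent rows are flagged and excluded from the surrogate fit;
    if fewer than ``min_converged_fraction`` of the rows converge the batch
    fails."""
    rows = []
    enc = dm.encoded()
    for r, codes in enumerate(dm.codes):
        config = decode_codes(codes, dm.space)
        result = run_instrumentation(spine, config, stiffness_cfg, segments)
        rec = {f"code{j}": int(c) for j, c in enumerate(codes)}
        rec.update({f"x{j}": float(v) for j, v in enumerate(enc[r])})
        rec.update({
            "uiv": config.uiv, "liv": config.liv,
            "n_implants": config.n_implants,
            "n_fused_levels": config.fused_levels,
            "converged": bool(result.converged),
        })
        if result.converged:
            d = result.post_descriptors.as_dict()
            rec.update({k: d[k] for k in RESPONSE_FIELDS})
            rec["F"] = d["F"]
        else:
            rec.update({k: np.nan for k in RESPONSE_FIELDS})
            rec["F"] = unfused_count((config.uiv, config.liv))
        rows.append(rec)
        if progress and (r + 1) % 50 == 0:
            log.info("run_batch: %d/%d simulations", r + 1, len(dm.codes))
    table = pd.DataFrame(rows)
    frac = table["converged"].mean()
    if frac < min_converged_fraction:
        raise BatchError(
            f"only {frac:.0%} of {len(table)} simulations converged "
            f"(minimum {min_converged_fraction:.0%})")
    return ResponseTable(table=table, space=dm.space)


# ---------------------------------------------------------------------------
# Surrogate regression
# ---------------------------------------------------------------------------

@dataclass
class SurrogateModel:
    """Per-descriptor main-effects linear model over the encoded variables."""

    coef: pd.DataFrame           # rows: intercept, x0..x5; columns: responses
    diagnostics: pd.DataFrame    # per response: r2, residual_sd, n
    space: DesignSpace

    def predict_matrix(self, X: np.ndarray) -> np.ndarray:
        """Predictions for encoded rows X (n x 6) -> (n x responses)."""
        Xd = np.column_stack([np.ones(len(X)), X])
        return Xd @ self.coef.to_numpy()


def fit_surrogate(rt: ResponseTable) -> SurrogateModel:
    """Ordinary least squares per descriptor (main effects only)."""
    conv = rt.converged_rows()
    xcols = [f"x{j}" for j in range(6)]
    X = conv[xcols].to_numpy(dtype=float)
    n, p = X.shape
    if n < 2 * (p + 1):
        raise FitError(f"only {n} converged rows for {p + 1} coefficients")
    for j, col in enumerate(xcols):
        if np.ptp(X[:, j]) < 1e-12:
            name = rt.space.variables[j][0]
            raise FitError(f"design is rank deficient: variable {name!r} is constant")
    Xd = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(Xd) < p + 1:
        raise FitError("design is rank deficient: collinear predictors")
    Y = conv[list(RESPONSE_FIELDS)].to_numpy(dtype=float)
    beta, _res, _rank, _sv = np.linalg.lstsq(Xd, Y, rcond=None)
    fitted = Xd @ beta
    resid = Y - fitted
    ss_res = (resid**2).sum(axis=0)
    ss_tot = ((Y - Y.mean(axis=0))**2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 1.0)
    dof = max(n - (p + 1), 1)
    coef = pd.DataFrame(beta, index=["intercept"] + xcols,
                        columns=list(RESPONSE_FIELDS))
    diag = pd.DataFrame({
        "r2": r2,
        "residual_sd": np.sqrt(ss_res / dof),
        "n": n,
    }, index=list(RESPONSE_FIELDS))
    return SurrogateModel(coef=coef, diagnostics=diag, space=rt.space)


def predict_descriptors(sm: SurrogateModel, config: InstrumentationConfig,
                        space: DesignSpace | None = None) -> DescriptorSet:
    """Surrogate prediction for one strategy.

    Negative predictions of non-negative descriptors are clamped to 0 (and
    logged); the unfused count F is computed exactly from the configuration
    rather than regressed."""
    space = space or sm.space
    x = encode_config(config, space)
    pred = sm.predict_matrix(x[None, :])[0]
    values = {}
    for name, v in zip(RESPONSE_FIELDS, pred):
        if name in _NONNEG_FIELDS and v < 0:
            log.info("predict_descriptors: clamped %s from %.2f to 0", name, v)
            v = 0.0
        values[name] = float(v)
    values["F"] = unfused_count((config.uiv, config.liv))
    return DescriptorSet(**values)


# ---------------------------------------------------------------------------
# Objective minimization
# ---------------------------------------------------------------------------

@dataclass
class OptimalStrategy:
    """Result of the surrogate-objective minimization."""

    config: InstrumentationConfig
    codes: np.ndarray
    predicted: DescriptorSet
    predicted_phi: float
    continuous_phi: float
    verified: SimResult | None = None


def _phi_of_prediction(pred_row: np.ndarray, F: float,
                       ctx: ObjectiveContext, w: WeightProfile) -> float:
    values = {}
    for name, v in zip(RESPONSE_FIELDS, pred_row):
        if name in _NONNEG_FIELDS and v < 0:
            v = 0.0
        values[name] = float(v)
    d = DescriptorSet(**values, F=int(round(F)))
    return phi(d, ctx, w)


def minimize_phi(sm: SurrogateModel, ctx: ObjectiveContext, w: WeightProfile,
                 space: DesignSpace | None = None,
                 verify_on: SpineModel | None = None,
                 stiffness_cfg: StiffnessConfig | None = None,
                 segments: dict[str, SegmentDef] | None = None) -> OptimalStrategy:
    """Most favourable strategy for a weight profile.

    Stage 1 minimizes the surrogate-composed objective over the continuous
    [-1, 1]^6 relaxation (L-BFGS-B, multi-start from 8 corners plus the
    center, with the unfused count interpolated continuously from the
    UIV/LIV codes).  Stage 2 evaluates the objective exhaustively on the
    discrete grid, so the returned strategy is a true grid minimum of the
    surrogate objective; ties break toward fewer fused levels, then
    lexicographic (cephalad) UIV."""
    space = space or sm.space
    space.validate()
    q = np.array(space.level_counts, dtype=float)
    uiv_idx = np.array([level_index(l) for l in space.uiv_levels], dtype=float)
    liv_idx = np.array([level_index(l) for l in space.liv_levels], dtype=float)

    def F_continuous(x: np.ndarray) -> float:
        cu = (x[0] + 1.0) * (q[0] - 1.0) / 2.0
        cl = (x[1] + 1.0) * (q[1] - 1.0) / 2.0
        iu = np.interp(cu, np.arange(len(uiv_idx)), uiv_idx)
        il = np.interp(cl, np.arange(len(liv_idx)), liv_idx)
        return 17.0 - (il - iu + 1.0)

    def objective(x: np.ndarray) -> float:
        pred = sm.predict_matrix(x[None, :])[0]
        F = max(F_continuous(x), 1.0)
        return _phi_of_prediction(pred, F, ctx, w)

    starts = [np.zeros(6)]
    for signs in itertools.product((-1.0, 1.0), repeat=3):
        starts.append(np.array(signs * 2))
    best_cont = np.inf
    for x0 in starts:
        res = _scipy_minimize(objective, x0, method="L-BFGS-B",
                              bounds=[(-1.0, 1.0)] * 6)
        if res.fun < best_cont:
            best_cont = float(res.fun)

    # stage 2: exhaustive discrete evaluation (grid small by construction)
    codes_all = space.enumerate_codes()
    X = codes_to_unit(codes_all, space)
    preds = sm.predict_matrix(X)
    fused = []
    for row in codes_all:
        iu = level_index(space.uiv_levels[row[0]])
        il = level_index(space.liv_levels[row[1]])
        fused.append(il - iu + 1)
    fused = np.array(fused)
    phis = np.array([
        _phi_of_prediction(preds[i], 17 - fused[i], ctx, w)
        for i in range(len(codes_all))
    ])
    order = np.lexsort((codes_all[:, 0], fused, phis))
    ibest = order[0]
    config = decode_codes(codes_all[ibest], space)
    predicted = predict_descriptors(sm, config, space)
    predicted_phi = phi(predicted, ctx, w)
    verified = None
    if verify_on is not None:
        verified = run_instrumentation(verify_on, config, stiffness_cfg, segments)
    return OptimalStrategy(config=config, codes=codes_all[ibest],
                           predicted=predicted, predicted_phi=predicted_phi,
                           continuous_phi=best_cont, verified=verified)


# ---------------------------------------------------------------------------
# Strategy reporting
# ---------------------------------------------------------------------------

def load_published_strategies() -> pd.DataFrame:
    """Packaged table of the eleven published optimal strategies."""
    return pd.read_csv(_DATA_DIR / "published_strategies.csv")


def summarize_strategies(rows: pd.DataFrame) -> pd.DataFrame:
    """Per-column summary statistics of a strategy table.

    For every numeric column: min, max, arithmetic mean and population
    (N-divisor) standard deviation, plus the printed convention used in
    clinical reporting — means truncated to one decimal, SDs rounded to one
    decimal."""
    if len(rows) == 0:
        raise ValidationError("empty strategy table")
    num = rows.select_dtypes(include=[np.number])
    if num.shape[1] == 0:
        raise ValidationError("strategy table has no numeric columns")
    out = []
    for col in num.columns:
        v = num[col].to_numpy(dtype=float)
        mean = float(v.mean())
        sd = float(v.std(ddof=0))
        out.append({
            "column": col,
            "min": float(v.min()),
            "max": float(v.max()),
            "mean": mean,
            "sd_population": sd,
            "mean_printed": math.floor(mean * 10.0) / 10.0,
            "sd_printed": round(sd, 1),
        })
    return pd.DataFrame(out).set_index("column")
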