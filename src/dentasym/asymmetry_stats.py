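"""Fluctuating-asymmetry statistics on aligned shape data.

The central tool is a two-way mixed-model Procrustes ANOVA on tangent-space
shape coordinates with factors *individual* (random) and *side* (fixed), and
replicate digitizations providing the error stratum:

==============  =====================  =========================
effect          meaning                df (I individuals, R reps)
==============  =====================  =========================
individual      shape differences      I - 1
side            directional asymmetry  1
ind x side      fluctuating asymmetry  I - 1
error           digitizing error       2 I (R - 1)
==============  =====================  =========================

Degrees of freedom are counted on the observation scale (one observation =
one digitized configuration), sums of squares over all tangent coordinates.
F ratios follow the mixed-model convention: FA is tested over error, while
individual and side are tested over the interaction. Significance comes from
residual randomization: for each effect, residuals of the reduced model that
excludes it are permuted across observations, added back to the reduced
fitted values, and the F statistic recomputed; the p-value is
(1 + #{F* >= F_obs}) / (n_perm + 1).

Per-individual FA scoring follows the antimere-difference construction:
replicates averaged, left minus right, the sample directional asymmetry
subtracted, and the Euclidean norm over all coordinates taken. Isomere
(upper/lower molar) scores are averaged into a composite, which is log
transformed and z-standardised for use in regression models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ComputationError, ValidationError

_EFFECTS = ("ind", "side", "ind_x_side", "error")


@dataclass
class ProcrustesANOVATable:
    """Variance decomposition with permutation p-values.

    ``degenerate`` flags a zero error mean square (F undefined / infinite).
    """

    df: dict[str, int]
    ss: dict[str, float]
    ms: dict[str, float]
    r2: dict[str, float]
    f: dict[str, float]
    p: dict[str, float]
    n_perm: int
    seed: int | None
    degenerate: bool = False

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for eff in _EFFECTS + ("total",):
            rows.append(
                {
                    "Effects": {"ind_x_side": "ind x side (FA)"}.get(eff, eff),
                    "df": self.df.get(eff),
                    "SS": self.ss.get(eff),
                    "MS": self.ms.get(eff),
                    "R2": self.r2.get(eff),
                    "F": self.f.get(eff),
                    "p": self.p.get(eff),
                }
            )
        return pd.DataFrame(rows)


@dataclass
class DirectionalAsymmetryEstimate:
    tooth_class: str
    mean_diff: np.ndarray  # flattened mean left-minus-right vector


@dataclass
class FAScoreRecord:
    individual_id: str
    fa_um1: float | None
    fa_lm1: float | None
    composite_fa: float
    fa_z: float = float("nan")


@dataclass
class GroupComparison:
    t: float
    df: float
    p: float
    cohens_d: float


@dataclass
class OneWayANOVA:
    f: float
    df_between: int
    df_within: int
    p: float


def _balanced_cube(
    shapes: np.ndarray, individual: np.ndarray, side: np.ndarray, replicate: np.ndarray
) -> tuple[np.ndarray, list, list, list]:
    """Arrange (N, K) observations into an (I, 2, R, K) cube; error if unbalanced."""
    inds = list(dict.fromkeys(individual))
    sides = sorted(set(side))
    reps = sorted(set(replicate))
    if len(sides) != 2:
        raise ValidationError(f"need exactly 2 sides, got {sides}")
    if len(reps) < 2:
        raise ValidationError("error term undefined with a single replicate")
    cube = np.full((len(inds), 2, len(reps), shapes.shape[1]), np.nan)
    ind_ix = {v: i for i, v in enumerate(inds)}
    side_ix = {v: i for i, v in enumerate(sides)}
    rep_ix = {v: i for i, v in enumerate(reps)}
    for row, (i, s, r) in enumerate(zip(individual, side, replicate)):
        cube[ind_ix[i], side_ix[s], rep_ix[r]] = shapes[row]
    if np.isnan(cube).any():
        raise ValidationError(
            "unbalanced design: every individual needs both sides and all replicates"
        )
    return cube, inds, sides, reps


def _anova_ss(cube: np.ndarray) -> tuple[float, float, float, float, float]:
    """Sequential (balanced) sums of squares for the two-way design."""
    i_n, _, r_n, _ = cube.shape
    grand = cube.mean(axis=(0, 1, 2))
    m_ind = cube.mean(axis=(1, 2))  # (I, K)
    m_side = cube.mean(axis=(0, 2))  # (2, K)
    m_cell = cube.mean(axis=2)  # (I, 2, K)
    ss_ind = 2 * r_n * float(((m_ind - grand) ** 2).sum())
    ss_side = i_n * r_n * float(((m_side - grand) ** 2).sum())
    inter = m_cell - m_ind[:, None, :] - m_side[None, :, :] + grand
    ss_int = r_n * float((inter**2).sum())
    ss_err = float(((cube - m_cell[:, :, None, :]) ** 2).sum())
    ss_tot = float(((cube - grand) ** 2).sum())
    return ss_ind, ss_side, ss_int, ss_err, ss_tot


def _f_stats(cube: np.ndarray, df: dict[str, int]) -> tuple[dict[str, float], bool]:
    ss_ind, ss_side, ss_int, ss_err, _ = _anova_ss(cube)
    ms = {
        "ind": ss_ind / df["ind"],
        "side": ss_side / df["side"],
        "ind_x_side": ss_int / df["ind_x_side"],
        "error": ss_err / df["error"],
    }
    degenerate = ms["error"] <= 0 or ms["ind_x_side"] <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        f = {
            "ind_x_side": ms["ind_x_side"] / ms["error"] if ms["error"] > 0 else np.inf,
            "side": ms["side"] / ms["ind_x_side"] if ms["ind_x_side"] > 0 else np.inf,
            "ind": ms["ind"] / ms["ind_x_side"] if ms["ind_x_side"] > 0 else np.inf,
        }
    return f, degenerate


def procrustes_anova(
    shapes: np.ndarray,
    individual: np.ndarray,
    side: np.ndarray,
    replicate: np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
) -> ProcrustesANOVATable:
    """Two-way mixed-model Procrustes ANOVA with residual randomization.

    Parameters
    ----------
    shapes
        (N, K) matrix of flattened tangent-space coordinates, one row per
        digitized configuration.
    individual, side, replicate
        length-N label arrays; the design must be balanced.
    n_perm
        number of residual-randomization permutations per effect; 0 skips
        p-values (df/SS/R2/F still reported).
    """
    shapes = np.asarray(shapes, dtype=float)
    cube, inds, _, reps = _balanced_cube(
        shapes, np.asarray(individual), np.asarray(side), np.asarray(replicate)
    )
    i_n, _, r_n, k = cube.shape
    if i_n < 2:
        raise ValidationError("need at least two individuals")
    n_obs = i_n * 2 * r_n
    df = {
        "ind": i_n - 1,
        "side": 1,
        "ind_x_side": i_n - 1,
        "error": n_obs - 2 * i_n,
        "total": n_obs - 1,
    }

    ss_ind, ss_side, ss_int, ss_err, ss_tot = _anova_ss(cube)
    ss = {
        "ind": ss_ind,
        "side": ss_side,
        "ind_x_side": ss_int,
        "error": ss_err,
        "total": ss_tot,
    }
    ms = {e: ss[e] / df[e] for e in _EFFECTS}
    r2 = {e: ss[e] / ss_tot if ss_tot > 0 else np.nan for e in _EFFECTS}
    f_obs, degenerate = _f_stats(cube, df)

    p: dict[str, float] = {}
    if n_perm > 0 and not degenerate:
        rng = np.random.default_rng(seed)
        grand = cube.mean(axis=(0, 1, 2))
        m_ind = cube.mean(axis=(1, 2))
        m_side = cube.mean(axis=(0, 2))
        # reduced-model fitted values per effect (sequential order
        # ind -> side -> ind x side): each effect's null model contains the
        # terms preceding it.
        fitted_red = {
            "ind": np.broadcast_to(grand, cube.shape),
            "side": np.broadcast_to(m_ind[:, None, None, :], cube.shape),
            "ind_x_side": np.broadcast_to(
                (m_ind[:, None, :] + m_side[None, :, :] - grand)[:, :, None, :],
                cube.shape,
            ),
        }
        flat_shape = (n_obs, k)
        for eff in ("ind", "side", "ind_x_side"):
            fit = np.asarray(fitted_red[eff])
            resid = (cube - fit).reshape(flat_shape)
            count = 0
            for _ in range(n_perm):
                perm = rng.permutation(n_obs)
                pseudo = fit + resid[perm].reshape(cube.shape)
                f_perm, _ = _f_stats(pseudo, df)
                if f_perm[eff] >= f_obs[eff]:
                    count += 1
            p[eff] = (1 + count) / (n_perm + 1)

    f_out = {"ind": f_obs["ind"], "side": f_obs["side"], "ind_x_side": f_obs["ind_x_side"]}
    return ProcrustesANOVATable(
        df=df, ss=ss, ms=ms, r2=r2, f=f_out, p=p, n_perm=n_perm, seed=seed,
        degenerate=degenerate,
    )


def directional_asymmetry(
    left: np.ndarray, right: np.ndarray, tooth_class: str = ""
) -> DirectionalAsymmetryEstimate:
    """Sample directional asymmetry: mean over individuals of (left - right).

    *left* and *right* are (n_individuals, K) matrices of replicate-averaged
    flattened configurations, row-matched by individual.
    """
    left = np.atleast_2d(np.asarray(left, dtype=float))
    right = np.atleast_2d(np.asarray(right, dtype=float))
    if left.shape != right.shape:
        raise ValidationError("left and right matrices must match in shape")
    if left.shape[0] == 0:
        raise ValidationError("directional asymmetry needs at least one pair")
    return DirectionalAsymmetryEstimate(tooth_class, (left - right).mean(axis=0))


def individual_fa_score(
    left: np.ndarray, right: np.ndarray, da: DirectionalAsymmetryEstimate | np.ndarray
) -> float:
    """DA-corrected antimeric asymmetry magnitude for one individual.

    score = sqrt( sum over coordinates of [ (L - R) - DA ]^2 ).
    """
    l = np.ravel(np.asarray(left, dtype=float))
    r = np.ravel(np.asarray(right, dtype=float))
    d = da.mean_diff if isinstance(da, DirectionalAsymmetryEstimate) else np.ravel(da)
    if l.shape != r.shape or l.shape != d.shape:
        raise ValidationError("left, right and DA vectors must share a point count")
    return float(np.linalg.norm((l - r) - d))


def composite_and_standardize(
    scores: pd.DataFrame,
) -> tuple[pd.DataFrame, list[FAScoreRecord]]:
    """Composite FA per individual, then log transform and z-standardise.

    *scores* needs columns ``individual`` and at least one of ``fa_um1`` /
    ``fa_lm1`` (NaN = tooth class unavailable). The composite is the mean of
    the available isomere scores; ``fa_z`` is the z-score of ln(composite)
    (sample mean 0, SD 1).
    """
    df = scores.copy()
    iso_cols = [c for c in ("fa_um1", "fa_lm1") if c in df.columns]
    if not iso_cols:
        raise ValidationError("scores need an fa_um1 and/or fa_lm1 column")
    df["composite_fa"] = df[iso_cols].mean(axis=1, skipna=True)
    if df["composite_fa"].isna().any():
        bad = df.loc[df["composite_fa"].isna(), "individual"].tolist()
        raise ValidationError(f"individuals with no isomere score: {bad}")
    if (df["composite_fa"] <= 0).any():
        raise ComputationError(
            "zero composite FA score: log transform undefined "
            "(check for degenerate simulation settings such as zero FA variance)"
        )
    logc = np.log(df["composite_fa"].to_numpy())
    sd = logc.std(ddof=1)
    if sd <= 0 or not np.isfinite(sd):
        raise ComputationError("zero variance in log composite FA prevents scaling")
    df["fa_z"] = (logc - logc.mean()) / sd
    records = [
        FAScoreRecord(
            individual_id=str(row["individual"]),
            fa_um1=None if "fa_um1" not in df.columns or pd.isna(row.get("fa_um1")) else float(row["fa_um1"]),
            fa_lm1=None if "fa_lm1" not in df.columns or pd.isna(row.get("fa_lm1")) else float(row["fa_lm1"]),
            composite_fa=float(row["composite_fa"]),
            fa_z=float(row["fa_z"]),
        )
        for _, row in df.iterrows()
    ]
    return df, records


def compare_groups(x, y) -> GroupComparison:
    """Welch's t-test plus pooled-SD Cohen's d for two score groups."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("each group needs at least two observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx <= 0 and vy <= 0 and np.isclose(x.mean(), y.mean()):
        return GroupComparison(t=0.0, df=float(len(x) + len(y) - 2), p=1.0, cohens_d=0.0)
    nx, ny = len(x), len(y)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df_w = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2 * stats.t.sf(abs(t), df_w)
    sp = np.sqrt(((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2))
    d = (x.mean() - y.mean()) / sp if sp > 0 else np.inf
    return GroupComparison(t=float(t), df=float(df_w), p=float(p), cohens_d=float(d))


@dataclass
class ToothClassAnalysis:
    """End-to-end FA analysis of one tooth class.

    Holds the joint alignment (right antimeres reflected into the left
    orientation, all replicates, one GPA), the Procrustes ANOVA, the sample
    directional asymmetry, and per-individual FA scores.
    """

    tooth_class: str
    anova: ProcrustesANOVATable
    da: DirectionalAsymmetryEstimate
    scores: pd.DataFrame  # columns: individual, fa
    n_pairs: int
    excluded: list[str] = field(default_factory=list)
    mean_shape: np.ndarray | None = None


def analyze_tooth_class(
    config_set,
    n_perm: int = 999,
    seed: int | None = None,
    n_cycles: int = 3,
    n_sweeps: int = 1,
) -> ToothClassAnalysis:
    """Run the full FA workflow for one tooth class.

    Steps: pair antimeres -> reflect right configurations -> slide
    semilandmarks + joint GPA over every configuration -> project to tangent
    space -> Procrustes ANOVA on all replicates -> replicate-average ->
    directional asymmetry -> per-individual FA scores.
    """
    from .landmark_io import pair_antimeres, reflect_configuration
    from .shape_align import align_with_sliding, project_to_tangent

    pairs, excluded = pair_antimeres(config_set)
    if not pairs:
        raise ValidationError("no complete antimere pairs in the configuration set")
    configs = []
    for pair in pairs:
        configs.extend(pair.left)
        configs.extend(reflect_configuration(c) for c in pair.right)
    result = align_with_sliding(
        configs, config_set.scheme, n_cycles=n_cycles, n_sweeps=n_sweeps
    )
    mean = result.mean_shape
    tangent = np.stack([project_to_tangent(a, mean).vector for a in result.aligned])
    ind = np.array([a.individual_id for a in result.aligned])
    side = np.array([a.side for a in result.aligned])
    rep = np.array([a.replicate for a in result.aligned])
    table = procrustes_anova(tangent, ind, side, rep, n_perm=n_perm, seed=seed)

    order = [p.individual_id for p in pairs]
    left_avg = np.stack([tangent[(ind == i) & (side == "L")].mean(axis=0) for i in order])
    right_avg = np.stack([tangent[(ind == i) & (side == "R")].mean(axis=0) for i in order])
    da = directional_asymmetry(left_avg, right_avg, config_set.scheme.tooth_class)
    fa = [individual_fa_score(left_avg[j], right_avg[j], da) for j in range(len(order))]
    scores = pd.DataFrame({"individual": order, "fa": fa})
    return ToothClassAnalysis(
        tooth_class=config_set.scheme.tooth_class,
        anova=table,
        da=da,
        scores=scores,
        n_pairs=len(pairs),
        excluded=excluded,
        mean_shape=mean,
    )


def oneway_anova(groups: list[np.ndarray]) -> OneWayANOVA:
    """One-way fixed-effects ANOVA across groups (e.g., FA scores by site)."""
    if len(groups) < 2:
        raise ValidationError("one-way ANOVA needs at least two groups")
    f, p = stats.f_oneway(*groups)
    df_b = len(groups) - 1
    df_w = sum(len(g) for g in groups) - len(groups)
    return OneWayANOVA(f=float(f), df_between=df_b, df_within=df_w, p=float(p))
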