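"""Shape alignment: GPA, sliding semilandmarks, tangent-space projection.

The goal of this module is to isolate *shape* — what remains of a landmark
configuration after translation, scale and rotation are removed — so that
left/right asymmetry can be measured in a common coordinate frame.

Pipeline: semilandmarks are slid along tangent directions to minimise the
thin-plate-spline bending energy of their deformation from a reference shape
(removing arbitrary variation in outline point spacing), configurations are
superimposed by Generalized Procrustes Analysis (iterative translation,
scaling to unit centroid size, and proper rotation to a running mean), and
the aligned shapes are projected from Kendall's shape space into the linear
tangent space at the mean, where Euclidean statistics apply.

Rotations are always proper (no reflection): antimere reflection is handled
explicitly upstream, so a reflection appearing during alignment would hide a
genuine asymmetry signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .errors import DegenerateConfigurationError, SingularBendingEnergyError, ValidationError
from .landmark_io import DigitizedConfiguration, LandmarkScheme


@dataclass
class AlignedConfiguration:
    """A configuration after superimposition: unit size, centred, rotated."""

    individual_id: str
    site: str
    tooth_class: str
    side: str
    replicate: int
    coords: np.ndarray  # (n_points, 2), centred, unit centroid size
    centroid_size: float  # pre-scaling size, retained as metadata
    reflected: bool = False

    @property
    def flat(self) -> np.ndarray:
        return self.coords.ravel()


@dataclass
class GPAResult:
    mean_shape: np.ndarray  # (n_points, 2), unit centroid size
    aligned: list[AlignedConfiguration]
    iterations: int
    converged: bool
    final_change: float


@dataclass
class TangentShape:
    """Flattened shape vector projected onto the tangent plane at the mean."""

    vector: np.ndarray  # length 2 * n_points
    reference: str = "grand_mean"


def centroid_size(coords: np.ndarray) -> float:
    """Root summed squared distance of landmarks from their centroid."""
    centred = coords - coords.mean(axis=0)
    return float(np.sqrt((centred**2).sum()))


def center_and_scale(config: DigitizedConfiguration) -> AlignedConfiguration:
    """Translate the centroid to the origin and scale to unit centroid size."""
    coords = config.coords - config.coords.mean(axis=0)
    size = float(np.sqrt((coords**2).sum()))
    if size <= 0 or not np.isfinite(size):
        raise DegenerateConfigurationError(
            f"configuration {config.label} has zero centroid size (all points coincide)"
        )
    return AlignedConfiguration(
        individual_id=config.individual_id,
        site=config.site,
        tooth_class=config.tooth_class,
        side=config.side,
        replicate=config.replicate,
        coords=coords / size,
        centroid_size=size,
        reflected=config.reflected,
    )


def optimal_rotation(coords: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper 2D rotation matrix R minimising ||coords @ R - target||.

    Closed form for the plane: the optimal angle is
    atan2(sum(x ∧ t), sum(x · t)).
    """
    dot = float((coords * target).sum())
    cross = float((coords[:, 0] * target[:, 1] - coords[:, 1] * target[:, 0]).sum())
    theta = np.arctan2(cross, dot)
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, s], [-s, c]])


def _rotate_all(stack: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotate each configuration in an (m, k, 2) stack onto *target*."""
    dot = np.einsum("mkc,kc->m", stack, target)
    cross = np.einsum("mk,k->m", stack[:, :, 0], target[:, 1]) - np.einsum(
        "mk,k->m", stack[:, :, 1], target[:, 0]
    )
    theta = np.arctan2(cross, dot)
    c, s = np.cos(theta), np.sin(theta)
    rot = np.empty((len(stack), 2, 2))
    rot[:, 0, 0] = c
    rot[:, 0, 1] = s
    rot[:, 1, 0] = -s
    rot[:, 1, 1] = c
    return np.einsum("mkc,mcd->mkd", stack, rot)


def gpa(
    configs: list[DigitizedConfiguration] | list[AlignedConfiguration],
    max_iter: int = 100,
    tol: float = 1e-10,
) -> GPAResult:
    """Generalized Procrustes Analysis with proper rotations only.

    Iterates rotate-to-mean / re-estimate-mean until the change in the mean
    shape's sum of squares falls below *tol*. The mean is renormalised to unit
    centroid size each iteration, so aligned configurations and the mean live
    on the unit pre-shape sphere.
    """
    if len(configs) < 2:
        raise ValidationError("GPA requires at least two configurations")
    pre: list[AlignedConfiguration] = []
    for cfg in configs:
        if isinstance(cfg, AlignedConfiguration):
            # re-centre/re-scale: upstream steps (sliding) may have nudged
            # the centroid or size off exactly (0, 0) / 1
            coords = cfg.coords - cfg.coords.mean(axis=0)
            size = np.sqrt((coords**2).sum())
            if size <= 0:
                raise DegenerateConfigurationError(
                    f"configuration {cfg.individual_id} has zero centroid size"
                )
            pre.append(replace(cfg, coords=coords / size))
        else:
            pre.append(center_and_scale(cfg))
    k = pre[0].coords.shape[0]
    if any(a.coords.shape[0] != k for a in pre):
        raise ValidationError("all configurations must share one landmark scheme")

    stack = np.stack([a.coords for a in pre])  # (m, k, 2)
    mean = stack[0].copy()
    mean /= np.sqrt((mean**2).sum())

    converged = False
    change = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        stack = _rotate_all(stack, mean)
        new_mean = stack.mean(axis=0)
        new_mean -= new_mean.mean(axis=0)
        norm = np.sqrt((new_mean**2).sum())
        if norm <= 0:
            raise DegenerateConfigurationError("GPA mean shape collapsed to a point")
        new_mean /= norm
        change = float(((new_mean - mean) ** 2).sum())
        mean = new_mean
        if change < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"GPA did not converge in {max_iter} iterations (last change {change:.3e})",
            stacklevel=2,
        )
    aligned = [replace(a, coords=stack[i]) for i, a in enumerate(pre)]
    return GPAResult(mean, aligned, it, converged, change)


# ---------------------------------------------------------------------------
# thin-plate-spline bending energy and semilandmark sliding
# ---------------------------------------------------------------------------


def bending_energy_matrix(reference: np.ndarray) -> np.ndarray:
    """Bending-energy matrix L_k of the 2D thin-plate spline at *reference*.

    For points p_i, the TPS kernel is U(r) = r^2 log(r^2). L_k is the upper
    k-by-k block of the inverse of the bordered system [[K, Q], [Q', 0]] with
    Q = [1 | x | y]; the bending energy of a displacement field v sampled at
    the reference points is v' L_k v per coordinate.
    """
    ref = np.asarray(reference, dtype=float)
    k = ref.shape[0]
    d2 = ((ref[:, None, :] - ref[None, :, :]) ** 2).sum(-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        kern = np.where(d2 > 0, d2 * np.log(d2), 0.0)
    q = np.hstack([np.ones((k, 1)), ref])
    lmat = np.zeros((k + 3, k + 3))
    lmat[:k, :k] = kern
    lmat[:k, k:] = q
    lmat[k:, :k] = q.T
    try:
        linv = np.linalg.inv(lmat)
    except np.linalg.LinAlgError as exc:
        raise SingularBendingEnergyError(
            "TPS system is singular (coincident reference points?)"
        ) from exc
    bem = linv[:k, :k]
    return (bem + bem.T) / 2.0  # symmetrise against round-off


def bending_energy(coords: np.ndarray, bem: np.ndarray) -> float:
    """Total bending energy of a configuration against a reference's L_k."""
    return float(np.einsum("kc,kl,lc->", coords, bem, coords))


def _tangent_directions(
    coords: np.ndarray, scheme: LandmarkScheme
) -> np.ndarray:
    """Unit tangent per semilandmark from the chord between outline neighbours.

    Interior semilandmarks use the chord joining their two neighbours along
    the outline; on an open curve the endpoints use the single adjacent chord.
    A closed outline has no endpoints (neighbours wrap).
    """
    semis = scheme.semi_indices
    pts = coords[semis]
    n = len(pts)
    tang = np.empty_like(pts)
    for j in range(n):
        if scheme.closed_outline:
            prev_pt, next_pt = pts[(j - 1) % n], pts[(j + 1) % n]
        elif j == 0:
            prev_pt, next_pt = pts[0], pts[1]
        elif j == n - 1:
            prev_pt, next_pt = pts[n - 2], pts[n - 1]
        else:
            prev_pt, next_pt = pts[j - 1], pts[j + 1]
        chord = next_pt - prev_pt
        norm = np.linalg.norm(chord)
        if norm <= 0:
            raise DegenerateConfigurationError(
                "coincident outline neighbours leave the tangent direction undefined"
            )
        tang[j] = chord / norm
    return tang


def slide_configuration(
    coords: np.ndarray,
    scheme: LandmarkScheme,
    bem: np.ndarray,
    label: str = "",
) -> np.ndarray:
    """One bending-energy sliding sweep of a single configuration.

    Each semilandmark j moves by t_j along its tangent u_j; the t that
    minimises the (quadratic) bending energy solves
    (u_j.u_l * L_k[j,l]) t = -u' L_k X for the semilandmark block. The move
    is the exact minimiser over the tangent-constrained subspace, which
    contains t = 0, so bending energy can never increase.
    """
    semis = scheme.semi_indices
    tang = _tangent_directions(coords, scheme)
    sub = bem[np.ix_(semis, semis)]
    a = sub * (tang @ tang.T)
    grad = bem @ coords  # (k, 2)
    b = (tang * grad[semis]).sum(axis=1)
    try:
        t = np.linalg.solve(a, -b)
    except np.linalg.LinAlgError as exc:
        raise SingularBendingEnergyError(
            f"singular sliding system for configuration {label or '<unnamed>'}"
        ) from exc
    out = coords.copy()
    out[semis] += t[:, None] * tang
    return out


def slide_semilandmarks(
    stack: np.ndarray,
    scheme: LandmarkScheme,
    mean: np.ndarray,
    n_sweeps: int = 1,
    labels: list[str] | None = None,
) -> np.ndarray:
    """Slide semilandmarks of every configuration in an (m, k, 2) stack.

    The bending-energy matrix is built once from *mean* (the reference);
    fixed landmarks are untouched. Returns a new stack.
    """
    bem = bending_energy_matrix(mean)
    out = np.array(stack, dtype=float, copy=True)
    for _ in range(n_sweeps):
        for i in range(len(out)):
            lab = labels[i] if labels else str(i)
            out[i] = slide_configuration(out[i], scheme, bem, label=lab)
    return out


def align_with_sliding(
    configs: list[DigitizedConfiguration],
    scheme: LandmarkScheme,
    n_cycles: int = 3,
    n_sweeps: int = 1,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> GPAResult:
    """Interleaved slide -> re-GPA alignment (the default analysis path).

    An initial GPA establishes a consensus; each cycle slides all
    semilandmarks against the current consensus (bending-energy criterion)
    and re-runs GPA. Three cycles are ample for well-separated outlines.
    """
    result = gpa(configs, max_iter=max_iter, tol=tol)
    labels = [a.individual_id + ":" + a.side + ":" + str(a.replicate) for a in result.aligned]
    for _ in range(n_cycles):
        stack = np.stack([a.coords for a in result.aligned])
        stack = slide_semilandmarks(stack, scheme, result.mean_shape, n_sweeps, labels)
        slid = [replace(a, coords=stack[i]) for i, a in enumerate(result.aligned)]
        result = gpa(slid, max_iter=max_iter, tol=tol)
    return result


def project_to_tangent(
    aligned: AlignedConfiguration | np.ndarray, mean: np.ndarray
) -> TangentShape:
    """Orthogonal projection onto the hyperplane tangent to the unit sphere
    at the mean shape.

    With unit vectors x and mu, the projection is x + (1 - x.mu) mu: the mean
    maps to itself, the map is idempotent, and for small Procrustes distances
    the tangent distance to the mean approximates the Procrustes distance.
    """
    x = aligned.flat if isinstance(aligned, AlignedConfiguration) else np.ravel(aligned)
    mu = np.ravel(mean)
    if x.shape != mu.shape:
        raise ValidationError("aligned shape and mean must share a point count")
    if np.linalg.norm(x) <= 0:
        raise ValidationError("zero-norm shape vector cannot be projected")
    mu = mu / np.linalg.norm(mu)
    return TangentShape(vector=x + (1.0 - x @ mu) * mu)


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Partial Procrustes distance between two configurations (no reflection).

    Both inputs are centred and scaled to unit size, the optimal proper
    rotation applied, and the Euclidean distance returned.
    """
    aa = a - a.mean(axis=0)
    bb = b - b.mean(axis=0)
    aa /= np.sqrt((aa**2).sum())
    bb /= np.sqrt((bb**2).sum())
    rot = optimal_rotation(aa, bb)
    return float(np.linalg.norm(aa @ rot - bb))
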