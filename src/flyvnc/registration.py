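"""Motion correction for two-channel two-photon stacks.

Recordings of the thoracic cervical connective suffer large inter-frame
translations plus smaller non-affine deformations. Registration proceeds in
two stages, both driven by the anatomy (red) channel because the calcium
indicator has low and activity-dependent baseline fluorescence:

1. center-of-mass (COM) registration removes large integer-pixel
   translations;
2. a variational optic-flow estimate of the dense residual motion field of
   each frame relative to the first recorded frame, with a quadratic
   (Horn-Schunck-type) smoothness penalty on the field gradient
   (weight ``lambda_smooth``, default 800), solved coarse-to-fine.

The estimated COM offsets and motion fields are then applied to *both*
channels with bilinear interpolation.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation
from skimage.transform import resize

from .datatypes import FrameStack, MotionField

__all__ = [
    "OpticFlowParams",
    "center_of_mass_register",
    "crop_center",
    "estimate_motion_field",
    "warp_bilinear",
    "correct_two_channel",
    "register_translation",
]


@dataclass
class OpticFlowParams:
    """Parameters of the variational motion-field estimator.

    lambda_smooth weights the squared-gradient penalty on the displacement
    field relative to the brightness-constancy data term; larger values
    give smoother (ultimately translation-only) fields. Images are
    rescaled internally to a fixed 0-255 dynamic range so the weight is
    comparable across acquisitions.
    """

    lambda_smooth: float = 800.0
    n_pyramid_levels: int = 3
    iterations_per_level: int = 100
    n_warps: int = 3
    convergence_tol: float = 1e-4  # mean |field change| in pixels
    presmooth_sigma: float = 1.0   # px, Gaussian blur before differentiation
    #: levels with at most this many pixels solve each linearization
    #: exactly (sparse direct solve); larger levels iterate
    exact_solve_max_px: int = 8000

    def __post_init__(self) -> None:
        if self.lambda_smooth <= 0:
            raise ValueError("lambda_smooth must be positive")
        if self.n_pyramid_levels < 1:
            raise ValueError("need at least one pyramid level")


# ---------------------------------------------------------------------------
# COM pre-alignment and cropping
# ---------------------------------------------------------------------------

def _center_of_mass(frame: np.ndarray) -> np.ndarray:
    # subtract the median (background level) so the COM tracks the bright
    # anatomy rather than the uniform background
    weight = np.clip(frame - np.median(frame), 0, None)
    total = weight.sum()
    if total == 0:
        return np.array([np.nan, np.nan])
    return np.array(ndimage.center_of_mass(weight))


def _integer_shift(frame: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Translate by an integer offset, filling exposed edges with 0."""
    out = np.zeros_like(frame)
    h, w = frame.shape
    ys = slice(max(dy, 0), min(h + dy, h))
    xs = slice(max(dx, 0), min(w + dx, w))
    ys_src = slice(max(-dy, 0), min(h - dy, h))
    xs_src = slice(max(-dx, 0), min(w - dx, w))
    out[ys, xs] = frame[ys_src, xs_src]
    return out


def center_of_mass_register(
    stack: FrameStack, reference_index: int = 0
) -> tuple[FrameStack, np.ndarray]:
    """Align each frame's intensity center of mass to a reference frame.

    Shifts are integer pixels (edge fill 0); subpixel residuals are left
    to the optic-flow stage. Returns the registered stack and the
    per-frame (dy, dx) offsets that were *applied*, for reuse on the
    paired channel.

    An all-zero frame has no defined center of mass: it is passed through
    with zero offset and a warning.
    """
    data = stack.data
    T = data.shape[0]
    if not (0 <= reference_index < T):
        raise ValueError(f"reference_index {reference_index} out of range")
    ref_com = _center_of_mass(data[reference_index])
    if np.any(np.isnan(ref_com)):
        warnings.warn("reference frame is all-zero; COM registration is a no-op")
        return stack.copy_with(data.copy()), np.zeros((T, 2), dtype=int)

    offsets = np.zeros((T, 2), dtype=int)
    out = np.empty_like(data)
    for t in range(T):
        com = _center_of_mass(data[t])
        if np.any(np.isnan(com)):
            warnings.warn(f"frame {t} is all-zero; passed through unshifted")
            out[t] = data[t]
            continue
        dy, dx = np.round(ref_com - com).astype(int)
        offsets[t] = (dy, dx)
        out[t] = _integer_shift(data[t], dy, dx)
    return stack.copy_with(out), offsets


def apply_com_offsets(stack: FrameStack, offsets: np.ndarray) -> FrameStack:
    """Apply previously computed integer COM offsets to a paired channel."""
    data = stack.data
    if offsets.shape[0] != data.shape[0]:
        raise ValueError("offset count does not match frame count")
    out = np.empty_like(data)
    for t in range(data.shape[0]):
        out[t] = _integer_shift(data[t], int(offsets[t, 0]), int(offsets[t, 1]))
    return stack.copy_with(out)


def crop_center(stack: FrameStack, target_height: int, target_width: int) -> FrameStack:
    """Centered crop; an odd margin removes the extra pixel from the
    high-index side (e.g. 10 -> 7 keeps indices 1..7)."""
    _, h, w = stack.shape
    if target_height > h or target_width > w:
        raise ValueError("crop target exceeds stack dimensions")
    y0 = (h - target_height) // 2
    x0 = (w - target_width) // 2
    return stack.copy_with(
        stack.data[:, y0 : y0 + target_height, x0 : x0 + target_width].copy()
    )


# ---------------------------------------------------------------------------
# Variational optic flow
# ---------------------------------------------------------------------------

# Horn-Schunck local-average kernel approximating the Laplacian as
# (mean of neighbours) - (centre value).
_AVG_KERNEL = np.array(
    [[1 / 12, 1 / 6, 1 / 12], [1 / 6, 0.0, 1 / 6], [1 / 12, 1 / 6, 1 / 12]]
)


def _normalize_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    scale = 255.0 / (hi - lo) if hi > lo else 1.0
    return (a - lo) * scale, (b - lo) * scale


def _hs_flow_energy(
    ix: np.ndarray, iy: np.ndarray, it: np.ndarray,
    du: np.ndarray, dv: np.ndarray, lam: float,
    u0: np.ndarray, v0: np.ndarray,
) -> float:
    """Linearized variational energy: data term + lambda * gradient penalty."""
    u, v = u0 + du, v0 + dv
    data = (ix * du + iy * dv + it) ** 2
    gy_u, gx_u = np.gradient(u)
    gy_v, gx_v = np.gradient(v)
    smooth = gy_u**2 + gx_u**2 + gy_v**2 + gx_v**2
    return float(data.sum() + lam * smooth.sum())


def _hs_iterate(
    ix: np.ndarray, iy: np.ndarray, it: np.ndarray,
    u: np.ndarray, v: np.ndarray, lam: float,
    n_iter: int, tol: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Jacobi-style Horn-Schunck iterations on one linearization.

    Iteratively solves the Euler-Lagrange equations of
    E = sum (Ix u + Iy v + It)^2 + lam * (|grad u|^2 + |grad v|^2)
    via the classical averaging update.
    """
    denom = lam + ix**2 + iy**2
    for _ in range(n_iter):
        u_bar = ndimage.convolve(u, _AVG_KERNEL, mode="nearest")
        v_bar = ndimage.convolve(v, _AVG_KERNEL, mode="nearest")
        common = (ix * u_bar + iy * v_bar + it) / denom
        u_new = u_bar - ix * common
        v_new = v_bar - iy * common
        change = 0.5 * (np.abs(u_new - u).mean() + np.abs(v_new - v).mean())
        u, v = u_new, v_new
        if change < tol:
            break
    return u, v


def _graph_laplacian(h: int, w: int) -> "sparse.csr_matrix":
    """5-point graph Laplacian with Neumann (no-flux) boundaries."""
    from scipy import sparse

    n = h * w
    idx = np.arange(n).reshape(h, w)
    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        src = idx[max(dy, 0) : h + min(dy, 0), max(dx, 0) : w + min(dx, 0)]
        dst = idx[max(-dy, 0) : h + min(-dy, 0), max(-dx, 0) : w + min(-dx, 0)]
        rows.append(src.ravel())
        cols.append(dst.ravel())
        vals.append(-np.ones(src.size))
        np.add.at(diag, src.ravel(), 1.0)
    lap = sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    return lap + sparse.diags(diag)


def _hs_solve_exact(
    ix: np.ndarray, iy: np.ndarray, it: np.ndarray, lam: float
) -> tuple[np.ndarray, np.ndarray]:
    """Direct sparse solve of one linearization's normal equations.

    The energy is quadratic, so its Euler-Lagrange system
    (lam * L + diag(Ix Ix)) u + diag(Ix Iy) v = -Ix It  (and symmetric in v)
    yields the exact minimizer; used on pyramid levels small enough for a
    sparse factorization, where iterative diffusion into untextured
    regions would be slow.
    """
    from scipy import sparse
    from scipy.sparse.linalg import spsolve

    h, w = ix.shape
    n = h * w
    lap = _graph_laplacian(h, w)
    fx, fy, ft = ix.ravel(), iy.ravel(), it.ravel()
    system = sparse.bmat(
        [
            [lam * lap + sparse.diags(fx * fx), sparse.diags(fx * fy)],
            [sparse.diags(fx * fy), lam * lap + sparse.diags(fy * fy)],
        ],
        format="csc",
    )
    rhs = -np.concatenate([fx * ft, fy * ft])
    sol = spsolve(system, rhs)
    return sol[:n].reshape(h, w), sol[n:].reshape(h, w)  # (u=dx, v=dy)


def _warp_image(img: np.ndarray, dy: np.ndarray, dx: np.ndarray) -> np.ndarray:
    h, w = img.shape
    yy, xx = np.mgrid[0:h, 0:w]
    coords = np.stack([yy + dy, xx + dx])
    return ndimage.map_coordinates(img, coords, order=1, mode="nearest")


def estimate_motion_field(
    frame: np.ndarray,
    reference: np.ndarray,
    params: OpticFlowParams | None = None,
    frame_index: int = 0,
    init_shift: tuple[float, float] = (0.0, 0.0),
) -> MotionField:
    """Estimate the dense displacement field warping ``frame`` onto
    ``reference``.

    Minimizes a brightness-constancy data term plus
    ``lambda_smooth`` times the squared gradient of the field,
    coarse-to-fine over a Gaussian pyramid with iterative re-warping at
    each level. ``init_shift`` seeds the field with a known translation
    (dy, dx), e.g. from COM pre-alignment, avoiding any intermediate
    resampling. The returned field follows the backward-warp convention:
    ``warp_bilinear(frame, field) ~= reference``.
    """
    params = params or OpticFlowParams()
    frame = np.asarray(frame, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if frame.shape != reference.shape:
        raise ValueError("frame and reference must have the same shape")
    if not (np.all(np.isfinite(frame)) and np.all(np.isfinite(reference))):
        raise ValueError("non-finite pixels in input images")

    if params.presmooth_sigma > 0:
        frame = ndimage.gaussian_filter(frame, params.presmooth_sigma)
        reference = ndimage.gaussian_filter(reference, params.presmooth_sigma)
    frame_n, ref_n = _normalize_pair(frame, reference)

    # Gaussian pyramid, coarsest first.
    pyramids = []
    f, r = frame_n, ref_n
    for level in range(params.n_pyramid_levels):
        pyramids.append((f, r))
        if level < params.n_pyramid_levels - 1:
            f = ndimage.gaussian_filter(f, 1.0)[::2, ::2]
            r = ndimage.gaussian_filter(r, 1.0)[::2, ::2]
    pyramids = pyramids[::-1]

    scale = 2.0 ** (params.n_pyramid_levels - 1)
    u = np.full_like(pyramids[0][0], init_shift[1] / scale)
    v = np.full_like(pyramids[0][0], init_shift[0] / scale)
    for level, (f_l, r_l) in enumerate(pyramids):
        if level > 0:
            u = 2.0 * resize(u, f_l.shape, order=1, anti_aliasing=False)
            v = 2.0 * resize(v, f_l.shape, order=1, anti_aliasing=False)
        for _ in range(params.n_warps):
            warped = _warp_image(f_l, v, u)  # v=dy, u=dx
            iy, ix = np.gradient(warped)
            it = warped - r_l
            if f_l.size <= params.exact_solve_max_px:
                du, dv = _hs_solve_exact(ix, iy, it, params.lambda_smooth)
            else:
                du, dv = _hs_iterate(
                    ix, iy, it,
                    np.zeros_like(u), np.zeros_like(v),
                    params.lambda_smooth,
                    params.iterations_per_level,
                    params.convergence_tol,
                )
            u = u + du
            v = v + dv
    return MotionField(dy=v, dx=u, frame_index=frame_index)


def warp_bilinear(frame: np.ndarray, field: MotionField) -> np.ndarray:
    """Backward-warp an image by a motion field with bilinear sampling.

    ``output(p) = frame(p + field(p))``; out-of-bounds samples take the
    nearest edge value.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.shape != field.shape:
        raise ValueError("frame and field shapes differ")
    return _warp_image(frame, field.dy, field.dx)


def correct_two_channel(
    red: FrameStack,
    green: FrameStack,
    reference_index: int = 0,
    params: OpticFlowParams | None = None,
    crop: tuple[int, int] | None = None,
) -> tuple[FrameStack, FrameStack, list[MotionField]]:
    """Full two-channel motion correction.

    COM offsets and dense motion fields are estimated on the red
    (anatomy) channel only; the identical total transform is applied to
    both channels. The COM shift is folded into the returned fields, so
    each field is the full displacement of its frame relative to the
    reference and each channel is interpolated exactly once. Optionally
    crops both stacks around the connective first.
    """
    if red.shape != green.shape:
        raise ValueError("red and green stacks must share shape")
    params = params or OpticFlowParams()

    if crop is not None:
        red = crop_center(red, *crop)
        green = crop_center(green, *crop)

    _, offsets = center_of_mass_register(red, reference_index)
    reference = red.data[reference_index]
    fields: list[MotionField] = []
    red_out = np.empty_like(red.data)
    green_out = np.empty_like(green.data)
    for t in range(red.n_frames):
        if t == reference_index:
            field = MotionField(
                dy=np.zeros_like(reference), dx=np.zeros_like(reference), frame_index=t
            )
        else:
            # the COM offset is the applied shift o; the equivalent backward
            # displacement -o seeds the flow, so no intermediate resampling
            # or edge fill touches the data
            field = estimate_motion_field(
                red.data[t],
                reference,
                params,
                frame_index=t,
                init_shift=(-float(offsets[t, 0]), -float(offsets[t, 1])),
            )
        fields.append(field)
        red_out[t] = warp_bilinear(red.data[t], field)
        green_out[t] = warp_bilinear(green.data[t], field)
    return red.copy_with(red_out), green.copy_with(green_out), fields


# ---------------------------------------------------------------------------
# Translation registration for longitudinal projections
# ---------------------------------------------------------------------------

def register_translation(image: np.ndarray, reference: np.ndarray) -> tuple[float, float]:
    """Subpixel translation (dy, dx) that maps ``reference`` onto ``image``.

    Cross-correlation with subpixel upsampling; both images are
    mean-subtracted and Hann-windowed first to suppress the circular
    edge artifacts that bias the correlation peak on smooth images. A
    constant image has no defined shift and returns (0, 0) with a warning.
    """
    from scipy.signal.windows import hann

    image = np.asarray(image, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if image.shape != reference.shape:
        raise ValueError("image and reference must have the same shape")
    if np.ptp(image) == 0 or np.ptp(reference) == 0:
        warnings.warn("constant image: translation undefined, returning (0, 0)")
        return (0.0, 0.0)
    window = np.outer(hann(image.shape[0]), hann(image.shape[1]))
    shift, _, _ = phase_cross_correlation(
        (reference - reference.mean()) * window,
        (image - image.mean()) * window,
        upsample_factor=50,
        normalization=None,
    )
    return (float(-shift[0]), float(-shift[1]))
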