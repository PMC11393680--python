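"""Vector geometry with optional forward-mode derivatives.

Every geometric construction in this package (atom placement, hydrogen
building) is written against the small set of operations in this module.
Each operation accepts either plain NumPy arrays or :class:`Dual` values
carrying a Jacobian with respect to an arbitrary parameter vector, so the
same code path yields both coordinates and their exact partial
derivatives.  This is the machinery that makes the whole builder
differentiable: a scalar loss downstream of the build can be chained
through these Jacobians analytically, with no finite differencing.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Dual",
    "is_dual",
    "value_of",
    "seed_params",
    "constant",
    "sin",
    "cos",
    "sqrt",
    "dot",
    "cross",
    "norm",
    "unit",
    "bond_angle",
    "dihedral",
]


class Dual:
    """A value paired with its Jacobian w.r.t. ``P`` scalar parameters.

    ``val`` has an arbitrary shape ``S`` (typically ``()`` for scalars or
    ``(3,)`` for points); ``jac`` has shape ``S + (P,)``.  Arithmetic
    follows the forward-mode chain rule.  Mixing with plain arrays or
    floats treats them as constants (zero derivative).
    """

    __slots__ = ("val", "jac")
    # keep NumPy from absorbing us into object arrays
    __array_ufunc__ = None

    def __init__(self, val, jac):
        self.val = np.asarray(val, dtype=float)
        self.jac = np.asarray(jac, dtype=float)

    @property
    def n_params(self) -> int:
        return self.jac.shape[-1]

    # -- helpers ---------------------------------------------------------
    def _coerce(self, other) -> "Dual":
        if isinstance(other, Dual):
            return other
        arr = np.asarray(other, dtype=float)
        return Dual(arr, np.zeros(arr.shape + (self.n_params,)))

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        o = self._coerce(other)
        return Dual(self.val + o.val, self.jac + o.jac)

    __radd__ = __add__

    def __sub__(self, other):
        o = self._coerce(other)
        return Dual(self.val - o.val, self.jac - o.jac)

    def __rsub__(self, other):
        o = self._coerce(other)
        return Dual(o.val - self.val, o.jac - self.jac)

    def __neg__(self):
        return Dual(-self.val, -self.jac)

    def __mul__(self, other):
        o = self._coerce(other)
        val = self.val * o.val
        jac = self.jac * o.val[..., None] + self.val[..., None] * o.jac
        return Dual(val, jac)

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = self._coerce(other)
        val = self.val / o.val
        jac = (self.jac * o.val[..., None] - self.val[..., None] * o.jac) / (
            o.val**2
        )[..., None]
        return Dual(val, jac)

    def __rtruediv__(self, other):
        return self._coerce(other).__truediv__(self)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Dual(val={self.val!r}, n_params={self.n_params})"


def is_dual(x) -> bool:
    return isinstance(x, Dual)


def value_of(x):
    """Plain ndarray/scalar value of ``x`` whether or not it is a Dual."""
    return x.val if isinstance(x, Dual) else np.asarray(x, dtype=float)


def seed_params(values) -> list[Dual]:
    """Wrap a 1-D parameter vector as scalar Duals with identity Jacobian."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    eye = np.eye(n)
    return [Dual(values[i], eye[i]) for i in range(n)]


def constant(x, n_params: int) -> Dual:
    arr = np.asarray(x, dtype=float)
    return Dual(arr, np.zeros(arr.shape + (n_params,)))


# ---------------------------------------------------------------------------
# elementary functions
# ---------------------------------------------------------------------------

def sin(x):
    if isinstance(x, Dual):
        return Dual(np.sin(x.val), np.cos(x.val)[..., None] * x.jac)
    return np.sin(x)


def cos(x):
    if isinstance(x, Dual):
        return Dual(np.cos(x.val), -np.sin(x.val)[..., None] * x.jac)
    return np.cos(x)


def sqrt(x):
    if isinstance(x, Dual):
        root = np.sqrt(x.val)
        return Dual(root, x.jac / (2.0 * root)[..., None])
    return np.sqrt(x)


def dot(a, b):
    if isinstance(a, Dual) or isinstance(b, Dual):
        if not isinstance(a, Dual):
            a = constant(a, b.n_params)
        if not isinstance(b, Dual):
            b = constant(b, a.n_params)
        val = float(np.dot(a.val, b.val))
        jac = b.val @ a.jac + a.val @ b.jac
        return Dual(val, jac)
    return float(np.dot(a, b))


def cross(a, b):
    if isinstance(a, Dual) or isinstance(b, Dual):
        if not isinstance(a, Dual):
            a = constant(a, b.n_params)
        if not isinstance(b, Dual):
            b = constant(b, a.n_params)
        val = np.cross(a.val, b.val)
        jac = np.cross(a.jac.T, b.val).T + np.cross(a.val, b.jac.T).T
        return Dual(val, jac)
    return np.cross(a, b)


def norm(v):
    return sqrt(dot(v, v))


def unit(v):
    return v / norm(v)


def vec3(x, y, z):
    """Assemble a 3-vector from scalars, any of which may be Dual."""
    comps = (x, y, z)
    duals = [c for c in comps if isinstance(c, Dual)]
    if not duals:
        return np.array([float(x), float(y), float(z)])
    n = duals[0].n_params
    val = np.array([value_of(c) for c in comps], dtype=float)
    jac = np.zeros((3, n))
    for i, c in enumerate(comps):
        if isinstance(c, Dual):
            jac[i] = c.jac
    return Dual(val, jac)


# ---------------------------------------------------------------------------
# internal-coordinate measurement (plain NumPy; used on concrete coordinates)
# ---------------------------------------------------------------------------

def bond_angle(p1, p2, p3) -> float:
    """Angle at ``p2`` in radians, in [0, pi]."""
    u = np.asarray(p1, float) - np.asarray(p2, float)
    v = np.asarray(p3, float) - np.asarray(p2, float)
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.arccos(np.clip(c, -1.0, 1.0)))


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion p1-p2-p3-p4 in radians, IUPAC convention, in (-pi, pi]."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    ang = -float(np.arctan2(y, x))
    if ang <= -np.pi:
        ang = np.pi
    return ang
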