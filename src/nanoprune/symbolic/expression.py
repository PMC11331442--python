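"""Expression trees with guarded numeric evaluation.

Operators are protected so that any expression evaluates to a finite
value at any finite input: division by near-zero returns 1, log and
sqrt operate on the absolute value (log of near-zero returns 0), and
exp is clipped.  Complexity is the plain node count.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Expression", "OPS", "BLOCK_SETS"]

_EPS = 1e-9
_EXP_CLIP = 50.0


def _div(a, b):
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(np.abs(b) < _EPS, 1.0, a / np.where(np.abs(b) < _EPS, 1.0, b))
    return out


def _plog(a):
    absa = np.abs(a)
    with np.errstate(divide="ignore"):
        return np.where(absa < _EPS, 0.0, np.log(np.where(absa < _EPS, 1.0, absa)))


def _psqrt(a):
    return np.sqrt(np.abs(a))


def _pexp(a):
    return np.exp(np.clip(a, -_EXP_CLIP, _EXP_CLIP))


#: name -> (arity, vectorized implementation, infix/func template)
OPS = {
    "add": (2, np.add, "({0} + {1})"),
    "sub": (2, np.subtract, "({0} - {1})"),
    "mul": (2, np.multiply, "({0} * {1})"),
    "div": (2, _div, "({0} / {1})"),
    "log": (1, _plog, "log({0})"),
    "sqrt": (1, _psqrt, "sqrt({0})"),
    "exp": (1, _pexp, "exp({0})"),
}

#: operator vocabularies for the two canonical building-block sets
BLOCK_SETS = {
    "rational_polynomial": ("add", "sub", "mul", "div"),
    "rational_plus_translog": ("add", "sub", "mul", "div", "log", "sqrt", "exp"),
}


class Expression:
    """A mutable expression tree node.

    ``op`` is an operator name from :data:`OPS`, or ``"var"`` (with
    ``var`` the predictor index) or ``"const"`` (with ``value`` the
    constant).
    """

    __slots__ = ("op", "children", "value", "var")

    def __init__(self, op, children=(), value=None, var=None):
        self.op = op
        self.children = list(children)
        self.value = value
        self.var = var
        if op in OPS and len(children) != OPS[op][0]:
            raise ValueError(f"operator {op} expects {OPS[op][0]} children")

    # -- constructors -------------------------------------------------
    @staticmethod
    def variable(index: int) -> "Expression":
        return Expression("var", var=index)

    @staticmethod
    def constant(value: float) -> "Expression":
        return Expression("const", value=float(value))

    # -- structure ----------------------------------------------------
    @property
    def complexity(self) -> int:
        return len(self.nodes())

    def nodes(self) -> list["Expression"]:
        out = []
        stack = [self]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return out

    def variables(self) -> set[int]:
        if self.op == "var":
            return {self.var}
        out: set[int] = set()
        for c in self.children:
            out |= c.variables()
        return out

    def constant_nodes(self) -> list["Expression"]:
        return [n for n in self.nodes() if n.op == "const"]

    def clone(self) -> "Expression":
        return Expression(
            self.op,
            [c.clone() for c in self.children],
            value=self.value,
            var=self.var,
        )

    # -- evaluation ---------------------------------------------------
    def eval(self, X: np.ndarray) -> np.ndarray:
        """Evaluate over a (n_rows, n_vars) matrix; always finite for finite X."""
        if self.op == "var":
            return X[:, self.var]
        if self.op == "const":
            return np.full(X.shape[0], self.value)
        fn = OPS[self.op][1]
        args = [c.eval(X) for c in self.children]
        # overflow in unprotected arithmetic (huge products) may yield
        # non-finite values; callers penalize those fitness-side
        return fn(*args)

    # -- rendering ----------------------------------------------------
    def to_str(self, names: list[str] | None = None) -> str:
        if self.op == "var":
            return names[self.var] if names else f"x{self.var}"
        if self.op == "const":
            return f"{self.value:.6g}"
        tmpl = OPS[self.op][2]
        return tmpl.format(*(c.to_str(names) for c in self.children))

    def __repr__(self) -> str:
        return f"Expression({self.to_str()})"

    def __eq__(self, other) -> bool:
        if not isinstance(other, Expression):
            return NotImplemented
        return self.to_str() == other.to_str()

    def __hash__(self) -> int:
        return hash(self.to_str())
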