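"""Expression-constrained flux balance analysis (E-Flux).

Gene-protein-reaction (GPR) rules are boolean expressions over genes
attached to reactions.  A rule's numeric value under a tumour's protein
abundances is computed with **sums for OR** (isoenzymes add capacity) and
**minimums for AND** (complex subunits limit each other).  Per tumour the
rule values are normalised by their maximum, and the normalised value v of
a reaction caps its flux: upper bound v*U, lower bound -v*U if the
reaction is reversible and 0 otherwise.  Biomass production is then the
optimum of the linear program

    max c'v  s.t.  S v = 0,  lb <= v <= ub.

Genes missing from the abundance map are dropped from their parent
operator (no evidence, not zero) so an unmeasured subunit does not block
a whole complex; a rule with no measured gene leaves the reaction
unconstrained.

A small Warburg-style network (glycolysis, glutaminolysis, lactate export,
a capped oxidative step and a biomass sink) ships with the package for
fully checkable analyses; SBML Level 3 FBC models can be loaded when the
optional cobra dependency is present.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from scipy.optimize import linprog

__all__ = [
    "GprExpr",
    "Gene",
    "And",
    "Or",
    "parse_gpr",
    "eval_gpr",
    "Reaction",
    "MetabolicModel",
    "FluxResult",
    "load_yaml_model",
    "load_toy_model",
    "load_sbml_model",
    "reaction_gpr_values",
    "normalize_gpr",
    "apply_eflux",
    "fba_optimize",
    "growth_by_group",
    "GrowthComparison",
]

DEFAULT_BOUND = 1000.0


# ---------------------------------------------------------------------------
# GPR expression trees


@dataclass(frozen=True)
class Gene:
    name: str


@dataclass(frozen=True)
class And:
    children: tuple


@dataclass(frozen=True)
class Or:
    children: tuple


GprExpr = Gene | And | Or

_TOKEN = re.compile(r"\s*(\(|\)|[^\s()]+)")


class GprSyntaxError(ValueError):
    pass


def _tokenize(text: str) -> list[tuple[str, int]]:
    tokens, pos = [], 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            break
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


def parse_gpr(text: str) -> GprExpr:
    """Parse a Recon-style GPR rule.

    Grammar: ``GENE | (expr) | expr and expr | expr or expr`` with
    case-insensitive keywords; ``and`` binds tighter than ``or``.
    """
    tokens = _tokenize(text)
    if not tokens:
        raise GprSyntaxError("empty GPR expression")
    idx = 0

    def peek():
        return tokens[idx][0] if idx < len(tokens) else None

    def error(msg):
        pos = tokens[idx][1] if idx < len(tokens) else len(text)
        raise GprSyntaxError(f"{msg} at position {pos}: {text!r}")

    def parse_or():
        nonlocal idx
        parts = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            idx += 1
            parts.append(parse_and())
        return parts[0] if len(parts) == 1 else Or(tuple(parts))

    def parse_and():
        nonlocal idx
        parts = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            idx += 1
            parts.append(parse_atom())
        return parts[0] if len(parts) == 1 else And(tuple(parts))

    def parse_atom():
        nonlocal idx
        tok = peek()
        if tok is None:
            error("unexpected end of expression")
        if tok == "(":
            idx += 1
            inner = parse_or()
            if peek() != ")":
                error("expected ')'")
            idx += 1
            return inner
        if tok == ")" or tok.lower() in ("and", "or"):
            error(f"unexpected token {tok!r}")
        idx += 1
        return Gene(tok)

    expr = parse_or()
    if idx != len(tokens):
        error(f"trailing token {tokens[idx][0]!r}")
    return expr


def eval_gpr(expr: GprExpr, abundance) -> float | None:
    """Numeric GPR value: OR = sum of children, AND = min of children.

    Genes absent from ``abundance`` are dropped from their parent operator;
    an expression with no measured gene evaluates to None (no evidence).
    """
    if isinstance(expr, Gene):
        v = abundance.get(expr.name)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return None
        if v < 0:
            raise ValueError(f"negative abundance for gene {expr.name}")
        return float(v)
    vals = [eval_gpr(c, abundance) for c in expr.children]
    vals = [v for v in vals if v is not None]
    if not vals:
        return None
    return float(sum(vals)) if isinstance(expr, Or) else float(min(vals))


def gpr_genes(expr: GprExpr) -> set[str]:
    if isinstance(expr, Gene):
        return {expr.name}
    out: set[str] = set()
    for c in expr.children:
        out |= gpr_genes(c)
    return out


# ---------------------------------------------------------------------------
# Metabolic model


@dataclass
class Reaction:
    id: str
    stoich: dict                     # metabolite -> coefficient (<0 consumed)
    reversible: bool = False
    lb: float = 0.0
    ub: float = DEFAULT_BOUND
    gpr: GprExpr | None = None

    def __post_init__(self) -> None:
        if not self.reversible and self.lb < 0:
            raise ValueError(f"{self.id}: irreversible reaction with lb < 0")


@dataclass
class MetabolicModel:
    metabolites: list
    reactions: list
    objective: str
    name: str = "model"

    def __post_init__(self) -> None:
        mets = set(self.metabolites)
        ids = [r.id for r in self.reactions]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate reaction ids")
        for r in self.reactions:
            unknown = set(r.stoich) - mets
            if unknown:
                raise ValueError(f"{r.id} references undeclared metabolites {unknown}")
        if self.objective not in ids:
            raise ValueError(f"objective reaction {self.objective!r} not in model")

    def reaction(self, rid: str) -> Reaction:
        return next(r for r in self.reactions if r.id == rid)

    def stoichiometric_matrix(self) -> pd.DataFrame:
        s = pd.DataFrame(
            0.0, index=self.metabolites, columns=[r.id for r in self.reactions]
        )
        for r in self.reactions:
            for met, coef in r.stoich.items():
                s.loc[met, r.id] = coef
        return s


@dataclass
class FluxResult:
    fluxes: pd.Series
    objective_value: float
    status: str

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


def load_yaml_model(path: str | Path) -> MetabolicModel:
    """Read a metabolic model from the package's YAML dialect."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    reactions = []
    for spec in doc["reactions"]:
        gpr = parse_gpr(spec["gpr"]) if spec.get("gpr") else None
        rev = bool(spec.get("reversible", False))
        reactions.append(
            Reaction(
                id=spec["id"],
                stoich=dict(spec["stoich"]),
                reversible=rev,
                lb=float(spec.get("lb", -DEFAULT_BOUND if rev else 0.0)),
                ub=float(spec.get("ub", DEFAULT_BOUND)),
                gpr=gpr,
            )
        )
    return MetabolicModel(
        metabolites=list(doc["metabolites"]),
        reactions=reactions,
        objective=doc["objective"],
        name=doc.get("name", Path(path).stem),
    )


def load_toy_model(name: str = "toy_warburg") -> MetabolicModel:
    """Load a bundled toy network (``toy_warburg`` or ``toy_chain``)."""
    ref = resources.files("tnlike.data") / f"{name}.yml"
    with resources.as_file(ref) as path:
        return load_yaml_model(path)


def load_sbml_model(path: str | Path) -> MetabolicModel:
    """Read an SBML Level 3 FBC model (requires the optional cobra extra)."""
    import cobra.io

    cm = cobra.io.read_sbml_model(str(path))
    reactions = []
    for r in cm.reactions:
        gpr_text = r.gene_reaction_rule
        reactions.append(
            Reaction(
                id=r.id,
                stoich={m.id: coef for m, coef in r.metabolites.items()},
                reversible=r.lower_bound < 0,
                lb=float(r.lower_bound),
                ub=float(r.upper_bound),
                gpr=parse_gpr(gpr_text) if gpr_text.strip() else None,
            )
        )
    objective = None
    for r in cm.reactions:
        if r.objective_coefficient:
            objective = r.id
            break
    if objective is None:
        raise ValueError("SBML model has no objective reaction")
    return MetabolicModel(
        metabolites=[m.id for m in cm.metabolites],
        reactions=reactions,
        objective=objective,
        name=cm.id or Path(path).stem,
    )


# ---------------------------------------------------------------------------
# E-Flux


def reaction_gpr_values(model: MetabolicModel, abundance) -> dict:
    """Raw GPR values for every reaction whose rule has measured genes."""
    out = {}
    for r in model.reactions:
        if r.gpr is None:
            continue
        v = eval_gpr(r.gpr, abundance)
        if v is not None:
            out[r.id] = v
    return out


def normalize_gpr(values) -> dict:
    """Divide each tumour's GPR values by their maximum (result in [0,1])."""
    if isinstance(values, (pd.Series, dict)):
        keys = list(values.keys()) if isinstance(values, dict) else list(values.index)
        vals = np.asarray([values[k] for k in keys], dtype=float)
    else:
        keys = list(range(len(values)))
        vals = np.asarray(values, dtype=float)
    if np.any(vals < 0):
        raise ValueError("negative GPR value")
    vmax = vals.max() if len(vals) else 0.0
    if vmax <= 0:
        raise ValueError("all GPR values are zero; cannot normalise")
    return {k: float(v / vmax) for k, v in zip(keys, vals)}


def apply_eflux(
    model: MetabolicModel, normalized: dict, bound_scale: float = 1.0
) -> MetabolicModel:
    """Cap reaction bounds with normalised GPR values.

    A reaction with value v gets upper bound v*U; lower bound -v*U if
    reversible, 0 otherwise.  Reactions without a value keep their default
    bounds.
    """
    reactions = []
    for r in model.reactions:
        if r.id in normalized:
            v = normalized[r.id]
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{r.id}: normalised value {v} outside [0, 1]")
            lb = -v * bound_scale if r.reversible else 0.0
            reactions.append(replace(r, lb=lb, ub=v * bound_scale))
        else:
            reactions.append(replace(r))
    return MetabolicModel(
        metabolites=list(model.metabolites),
        reactions=reactions,
        objective=model.objective,
        name=model.name,
    )


def fba_optimize(model: MetabolicModel) -> FluxResult:
    """Maximise the objective flux subject to S v = 0 and the bounds."""
    s = model.stoichiometric_matrix().to_numpy()
    rids = [r.id for r in model.reactions]
    c = np.zeros(len(rids))
    c[rids.index(model.objective)] = -1.0  # linprog minimises
    bounds = [(r.lb, r.ub) for r in model.reactions]
    res = linprog(
        c, A_eq=s, b_eq=np.zeros(s.shape[0]), bounds=bounds, method="highs"
    )
    if res.status == 0:
        status = "optimal"
        fluxes = pd.Series(res.x, index=rids)
        obj = float(-res.fun)
    else:
        status = {2: "infeasible", 3: "unbounded"}.get(res.status, "failed")
        fluxes = pd.Series(np.nan, index=rids)
        obj = float("nan")
    return FluxResult(fluxes=fluxes, objective_value=obj, status=status)


@dataclass
class GrowthComparison:
    """Per-tumour predicted growth with between-group rank tests."""

    objectives: pd.Series            # per-tumour optimal biomass flux
    labels: pd.Series
    pvalues: dict                    # (group_a, group_b) -> Mann-Whitney p
    failed: list = field(default_factory=list)


def growth_by_group(
    model: MetabolicModel,
    abundance: pd.DataFrame,
    labels,
    bound_scale: float = 1.0,
    reference_group: str | None = None,
) -> GrowthComparison:
    """E-Flux biomass optimum per tumour, compared between groups.

    ``abundance`` is genes x tumours.  Each tumour's GPR values are
    normalised by their own maximum before constraining the model.  Groups
    with >= 3 solved tumours are compared with a two-sided Mann-Whitney U
    against ``reference_group`` (default: the first label level).
    """
    labels = pd.Series(np.asarray(labels), index=abundance.columns)
    objectives, failed = {}, []
    for sid in abundance.columns:
        ab = abundance[sid].dropna().to_dict()
        raw = reaction_gpr_values(model, ab)
        try:
            norm = normalize_gpr(raw) if raw else {}
        except ValueError:
            norm = {}
        result = fba_optimize(apply_eflux(model, norm, bound_scale))
        if result.ok:
            objectives[sid] = result.objective_value
        else:
            failed.append(sid)
    if failed:
        warnings.warn(f"FBA failed for {len(failed)} tumour(s); excluded")
    obj = pd.Series(objectives, name="growth")
    lab = labels.loc[obj.index]

    levels = list(pd.unique(labels))
    ref = reference_group if reference_group is not None else levels[0]
    pvals = {}
    for other in levels:
        if other == ref:
            continue
        a = obj[lab == ref]
        b = obj[lab == other]
        if len(a) >= 3 and len(b) >= 3:
            if a.nunique() == 1 and b.nunique() == 1 and a.iloc[0] == b.iloc[0]:
                pvals[(ref, other)] = 1.0
            else:
                pvals[(ref, other)] = float(
                    stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
                )
    return GrowthComparison(objectives=obj, labels=lab, pvalues=pvals, failed=failed)
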