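"""Synthetic regulatory networks and subtype-structured expression data.

The generator produces the structure the subtyping method is designed to
detect: regulator *families* with partially overlapping target sets
(fraction ``overlap_fraction`` of each regulator's targets is a family
core shared by all members, mimicking redundant paralogs), optional hub
genes wired to many regulators (high connectivity), and expression in
which each disease subtype up-shifts the targets of its active regulator
families by a mean log-ratio ``effect_size`` on top of per-gene noise
``noise_sd``.  Controls carry no active regulators.

Planted shifts are calibrated per sample (scalar root-find) so that the
*realized* mean log-ratio of the planted targets — after the pipeline's
own per-array standardization and averaged-control subtraction — equals
``effect_size``.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .expression import ExpressionMatrix
from .network import RegulatoryNetwork

_FAMILY_RE = re.compile(r"^(F\d+)R\d+$")


class SizingError(ValueError):
    """Requested structure does not fit into the gene pool."""


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated dataset."""

    subtype_labels: dict[str, str]          # sample -> group (incl. control)
    active_regulators: dict[str, frozenset[str]]   # subtype -> regulators
    active_families: dict[str, tuple[str, ...]]    # subtype -> families
    planted_genes: dict[str, frozenset[str]]       # subtype -> shifted genes
    effect_size: float
    noise_sd: float
    regulator_families: dict[str, str]      # regulator -> family
    control_group: str = "control"

    def to_json(self, path: str | Path) -> None:
        payload = {
            "subtype_labels": self.subtype_labels,
            "active_regulators": {k: sorted(v) for k, v in self.active_regulators.items()},
            "active_families": {k: list(v) for k, v in self.active_families.items()},
            "planted_genes": {k: sorted(v) for k, v in self.planted_genes.items()},
            "effect_size": self.effect_size,
            "noise_sd": self.noise_sd,
            "regulator_families": self.regulator_families,
            "control_group": self.control_group,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def regulator_families(network: RegulatoryNetwork) -> dict[str, str]:
    """Family partition of simulated regulators (parsed from ``F<i>R<j>`` ids)."""
    out: dict[str, str] = {}
    for seed in network.seeds:
        m = _FAMILY_RE.match(seed)
        out[seed] = m.group(1) if m else seed
    return out


def simulate_network(
    n_families: int,
    regulators_per_family: int,
    targets_per_regulator: int,
    overlap_fraction: float,
    n_background_genes: int,
    hub_fraction: float = 0.0,
    seed: int | None = None,
) -> RegulatoryNetwork:
    """Simulate a regulator→target network with family structure and hubs.

    Targets are drawn without replacement from a pool of
    ``n_background_genes`` gene ids, so regulators within a family share
    exactly ``ceil(overlap_fraction · targets_per_regulator)`` core
    targets and families are mutually disjoint (apart from hubs).  A
    ``hub_fraction`` of the pool becomes hub genes, each wired to a random
    30–70% of all regulators.
    """
    if min(n_families, regulators_per_family, targets_per_regulator,
           n_background_genes) < 1:
        raise ValueError("structure parameters must be positive")
    if not (0.0 <= overlap_fraction < 1.0):
        raise ValueError("overlap_fraction must be in [0, 1)")
    if not (0.0 <= hub_fraction < 1.0):
        raise ValueError("hub_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    t = targets_per_regulator
    n_core = math.ceil(overlap_fraction * t)
    per_family = n_core + regulators_per_family * (t - n_core)
    n_hubs = round(hub_fraction * n_background_genes)
    needed = n_families * per_family + n_hubs
    if needed > n_background_genes:
        raise SizingError(
            f"need {needed} distinct target genes but the pool has only "
            f"{n_background_genes}; shrink families/targets or grow the pool"
        )
    pool = [f"G{i + 1:05d}" for i in range(n_background_genes)]
    order = rng.permutation(n_background_genes)
    cursor = 0

    def take(n: int) -> list[str]:
        nonlocal cursor
        idx = order[cursor:cursor + n]
        cursor += n
        return [pool[i] for i in idx]

    edges: list[tuple[str, str, str]] = []
    regulators: list[str] = []
    for f in range(1, n_families + 1):
        core = take(n_core)
        for r in range(1, regulators_per_family + 1):
            name = f"F{f}R{r}"
            regulators.append(name)
            targets = core + take(t - n_core)
            edges.extend((name, g, "Expression") for g in targets)
    n_regs = len(regulators)
    lo = max(1, math.ceil(0.3 * n_regs))
    hi = max(lo, math.ceil(0.7 * n_regs))
    for g in take(n_hubs):
        n_w = int(rng.integers(lo, hi + 1))
        for reg in rng.choice(regulators, size=n_w, replace=False):
            edges.append((str(reg), g, "Expression"))
    return RegulatoryNetwork(edges)


def _standardize(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std()


def simulate_expression(
    network: RegulatoryNetwork,
    n_subtypes: int,
    samples_per_subtype: int,
    n_controls: int,
    active_per_subtype: int,
    effect_size: float,
    noise_sd: float,
    seed: int | None = None,
    n_background_genes: int = 1000,
    control_label: str = "control",
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Simulate raw intensities with planted subtype programs.

    The measured universe is all network genes plus ``n_background_genes``
    untargeted background genes.  Gene log-values are a shared baseline
    ``N(0, 1)`` plus per-sample noise ``N(0, noise_sd²)``; each disease
    sample's planted targets (the union of its subtype's active regulator
    targets) receive an additive log-space shift calibrated so the
    realized mean log-ratio equals ``effect_size``.  Output intensities
    are ``2**value`` (raw state, strictly positive).
    """
    if samples_per_subtype < 2 or n_controls < 2:
        raise ValueError("need at least 2 samples per group")
    if n_subtypes < 1:
        raise ValueError("need at least 1 subtype")
    if effect_size < 0:
        raise ValueError("effect_size must be >= 0")
    fam_of = regulator_families(network)
    families = sorted(set(fam_of.values()))
    if active_per_subtype > len(families):
        raise ValueError(
            f"active_per_subtype={active_per_subtype} exceeds the "
            f"{len(families)} regulator families"
        )
    rng = np.random.default_rng(seed)

    net_genes = sorted(network.genes)
    bg_genes = [f"B{i + 1:05d}" for i in range(n_background_genes)]
    genes = net_genes + bg_genes
    n_genes = len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}

    # family-wise subtype programs: disjoint round-robin when they fit,
    # otherwise random draws without replacement per subtype
    active_fams: dict[str, tuple[str, ...]] = {}
    subtype_names = [f"subtype{i + 1}" for i in range(n_subtypes)]
    if n_subtypes * active_per_subtype <= len(families):
        for i, st in enumerate(subtype_names):
            sel = families[i * active_per_subtype:(i + 1) * active_per_subtype]
            active_fams[st] = tuple(sel)
    else:
        for st in subtype_names:
            sel = rng.choice(families, size=active_per_subtype, replace=False)
            active_fams[st] = tuple(str(f) for f in sorted(sel))

    active_regs: dict[str, frozenset[str]] = {}
    planted: dict[str, frozenset[str]] = {}
    planted_idx: dict[str, np.ndarray] = {}
    for st in subtype_names:
        if effect_size == 0:
            active_regs[st] = frozenset()
            planted[st] = frozenset()
            planted_idx[st] = np.array([], dtype=int)
            continue
        regs = frozenset(r for r in network.seeds if fam_of[r] in active_fams[st])
        active_regs[st] = regs
        targets: set[str] = set()
        for r in regs:
            targets |= network.targets_of(r)
        planted[st] = frozenset(targets)
        planted_idx[st] = np.array(sorted(gene_pos[g] for g in targets), dtype=int)

    baseline = rng.normal(0.0, 1.0, size=n_genes)

    columns: dict[str, np.ndarray] = {}
    groups: dict[str, str] = {}
    ctrl_ids = [f"ctrl{i + 1:02d}" for i in range(n_controls)]
    ctrl_std = np.empty((n_genes, n_controls))
    for j, sid in enumerate(ctrl_ids):
        z = baseline + rng.normal(0.0, noise_sd, size=n_genes)
        ctrl_std[:, j] = _standardize(z)
        columns[sid] = z
        groups[sid] = control_label
    control_profile = ctrl_std.mean(axis=1)

    for st in subtype_names:
        idx = planted_idx[st]
        for i in range(samples_per_subtype):
            sid = f"{st}_s{i + 1:02d}"
            z0 = baseline + rng.normal(0.0, noise_sd, size=n_genes)
            if effect_size > 0 and idx.size:
                def gap(a: float) -> float:
                    col = z0.copy()
                    col[idx] += a
                    return float(
                        _standardize(col)[idx].mean()
                        - control_profile[idx].mean()
                        - effect_size
                    )
                a_hi = 100.0
                if gap(a_hi) <= 0:
                    f = idx.size / n_genes
                    raise SizingError(
                        f"effect_size={effect_size} infeasible for planted "
                        f"fraction {f:.3f} (max ~ sqrt((1-f)/f)); reduce the "
                        "effect or the planted set"
                    )
                a = brentq(gap, 0.0, a_hi, xtol=1e-10)
                z0 = z0.copy()
                z0[idx] += a
            columns[sid] = z0
            groups[sid] = st

    values = pd.DataFrame(
        {sid: np.exp2(col) for sid, col in columns.items()}, index=genes
    )
    matrix = ExpressionMatrix(
        values=values,
        groups=pd.Series(groups),
        control_group=control_label,
        state="raw",
    )
    truth = SyntheticTruth(
        subtype_labels=dict(groups),
        active_regulators=active_regs,
        active_families=active_fams,
        planted_genes=planted,
        effect_size=effect_size,
        noise_sd=noise_sd,
        regulator_families=fam_of,
        control_group=control_label,
    )
    return matrix, truth


# The study conditions for the synthetic benchmark and for the global-null
# calibration experiment.  The null preset uses disjoint target sets and
# no hubs so that every gene has connectivity 1 and per-seed tests are
# close to independent — the regime in which the 5% nominal level of the
# rank test is a meaningful calibration reference.
PRESETS: dict[str, dict] = {
    "default": {
        "network": {
            "n_families": 6,
            "regulators_per_family": 5,
            "targets_per_regulator": 20,
            "overlap_fraction": 0.6,
            "n_background_genes": 400,
            "hub_fraction": 0.02,
        },
        "expression": {
            "n_subtypes": 3,
            "samples_per_subtype": 10,
            "n_controls": 10,
            "active_per_subtype": 2,
            "effect_size": 2.0,
            "noise_sd": 0.3,
            "n_background_genes": 1000,
        },
    },
    "null": {
        "network": {
            "n_families": 5,
            "regulators_per_family": 5,
            "targets_per_regulator": 20,
            "overlap_fraction": 0.0,
            "n_background_genes": 600,
            "hub_fraction": 0.0,
        },
        "expression": {
            "n_subtypes": 2,
            "samples_per_subtype": 2,
            "n_controls": 5,
            "active_per_subtype": 2,
            "effect_size": 0.0,
            "noise_sd": 0.3,
            "n_background_genes": 800,
        },
    },
}


@dataclass
class SimulatedDataset:
    expression: ExpressionMatrix
    network: RegulatoryNetwork
    truth: SyntheticTruth


def simulate_dataset(
    preset: str = "default",
    seed: int | None = None,
    effect_size: float | None = None,
) -> SimulatedDataset:
    """Generate a full (expression, network, truth) dataset from a preset.

    ``effect_size`` may be overridden (e.g. for effect-size sweeps); all
    other conditions are fixed by the preset.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; have {sorted(PRESETS)}")
    cfg = PRESETS[preset]
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    net_seed, expr_seed = (int(c.generate_state(1)[0] % (2**31 - 1))
                           for c in ss.spawn(2))
    network = simulate_network(seed=net_seed, **cfg["network"])
    expr_kwargs = dict(cfg["expression"])
    if effect_size is not None:
        expr_kwargs["effect_size"] = effect_size
    expression, truth = simulate_expression(network, seed=expr_seed, **expr_kwargs)
    return SimulatedDataset(expression=expression, network=network, truth=truth)
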