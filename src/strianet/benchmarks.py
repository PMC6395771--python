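"""Standard evaluation studies on synthetic data with planted structure.

These drive both the test suite and the reproduction script: the
disrupted-module recovery study (full network/preservation chain at a
fixed design) and the differential-expression calibration study (type-I
error under the null, sensitivity and sign agreement on planted DEGs).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import diffexp as de
from . import network as net
from . import preprocess as pp
from . import preservation as pres
from . import simulate as sim

__all__ = [
    "recovery_design",
    "recovery_trial",
    "recovery_study",
    "de_calibration_trial",
]

#: study conditions of the module-recovery benchmark: three planted modules,
#: the middle (size-150) one disrupted in cases
RECOVERY_DESIGN = dict(
    n_genes=2000,
    n_case=20,
    n_control=20,
    module_sizes=[100, 150, 200],
    module_loadings=0.8,
    disrupted_module=1,
    n_deg=50,
    deg_log2fc=2.0,
    dispersion=0.05,
)
RECOVERY_BETA = 6
RECOVERY_MIN_MODULE_SIZE = 30


def recovery_design(seed: int) -> sim.SyntheticDesign:
    return sim.SyntheticDesign(seed=seed, **RECOVERY_DESIGN)


def recovery_trial(
    seed: int,
    n_perm: int = 100,
    with_truth_calibration: bool = False,
) -> dict:
    """One seed of the disrupted-module recovery study.

    Runs the full chain — simulate, normalize, control network, static-cut
    module detection, permutation preservation, least-preserved selection —
    and reports whether the selected module is the one carrying the planted
    disrupted block.  With ``with_truth_calibration`` the permutation Z
    scale is additionally evaluated on the planted module memberships
    (intact modules expected above the well-preserved bound of 10, the
    disrupted one below the weak-preservation bound of 2).
    """
    design = recovery_design(seed)
    case, ctrl, _, truth = sim.simulate_dataset(design)
    expr = pp.normalize_log(pd.concat([case, ctrl], axis=1))
    expr_ctrl = expr[ctrl.columns]
    expr_case = expr[case.columns]

    cor, _, _ = net.correlation_matrix(expr_ctrl)
    tom_sim = net.tom(net.adjacency(cor, RECOVERY_BETA))
    partition = net.detect_modules(1.0 - tom_sim, RECOVERY_MIN_MODULE_SIZE)
    mapped, _ = pres.map_reference_modules(partition, expr_case)
    stats = pres.permutation_null(
        expr_ctrl, expr_case, mapped, beta=RECOVERY_BETA,
        n_perm=n_perm, seed=seed + 1,
    )
    kme_ref = net.kme(expr_ctrl, net.module_eigengenes(expr_ctrl, mapped))
    kme_test = net.kme(expr_case, net.module_eigengenes(expr_case, mapped))
    selected, rationale = pres.select_least_preserved(stats, kme_ref, kme_test)

    disrupted = set(truth.module_genes(truth.disrupted_module))
    carrier = max(
        partition.module_ids,
        key=lambda m: len(disrupted & set(partition.genes(m))),
    )
    carrier_frac = len(disrupted & set(partition.genes(carrier))) / len(disrupted)
    out = {
        "seed": seed,
        "n_modules": len(partition.module_ids),
        "selected": int(selected),
        "carrier": int(carrier),
        "carrier_frac": carrier_frac,
        "hit": bool(selected == carrier and carrier_frac >= 0.5),
        "agreement": rationale.agreement,
    }

    if with_truth_calibration:
        planted = net.ModulePartition(
            labels=(truth.module_membership + 1).clip(lower=0),
            min_size=RECOVERY_MIN_MODULE_SIZE,
        )
        truth_stats = pres.permutation_null(
            expr_ctrl, expr_case, planted, beta=RECOVERY_BETA,
            n_perm=n_perm, seed=seed + 2,
        )
        zs = truth_stats.summary["Zsummary"]
        disrupted_label = truth.disrupted_module + 1
        intact = [m for m in zs.index if m != disrupted_label]
        out["z_intact_min"] = float(zs[intact].min())
        out["z_disrupted"] = float(zs[disrupted_label])
        out["calibrated"] = bool(out["z_intact_min"] > 10 and out["z_disrupted"] < 2)
    return out


def recovery_study(
    seeds, n_perm: int = 100, n_calibration: int = 10
) -> pd.DataFrame:
    """Recovery trials over ``seeds``; the first ``n_calibration`` also
    evaluate the planted-module Z calibration."""
    rows = [
        recovery_trial(s, n_perm=n_perm, with_truth_calibration=(i < n_calibration))
        for i, s in enumerate(seeds)
    ]
    return pd.DataFrame(rows)


def de_calibration_trial(seed: int, n_genes: int = 2000, n_per_group: int = 20) -> dict:
    """Type-I error under a null NB simulation plus planted-DEG sensitivity
    and sign agreement at |log2FC| = 2 in the relaxed (raw p <= 0.01) set."""
    null_design = sim.SyntheticDesign(
        n_genes=n_genes, n_case=n_per_group, n_control=n_per_group,
        module_sizes=[], disrupted_module=None, n_deg=0,
        dispersion=0.05, seed=seed,
    )
    case, ctrl, meta, _ = sim.simulate_dataset(null_design)
    counts = pd.concat([case, ctrl], axis=1)
    X = pp.build_design_matrix(meta, ["group"])
    tab = de.fit_nb_glm_wald(counts, X, "group_control")
    type1 = float((tab["p"] <= 0.05).mean())

    deg_design = sim.SyntheticDesign(
        n_genes=n_genes, n_case=n_per_group, n_control=n_per_group,
        module_sizes=[], disrupted_module=None, n_deg=50, deg_log2fc=2.0,
        dispersion=0.05, seed=seed + 1,
    )
    case, ctrl, meta, truth = sim.simulate_dataset(deg_design)
    counts = pd.concat([case, ctrl], axis=1)
    X = pp.build_design_matrix(meta, ["group"])
    tab = de.fit_nb_glm_wald(counts, X, "group_control")
    tab[["log2fc", "wald_z"]] *= -1.0  # orient case/control
    degs = de.call_degs(tab)
    planted = set(truth.deg_genes)
    recovered = planted & degs.relaxed
    sensitivity = len(recovered) / len(planted)
    truth_lfc = truth.deg_table.set_index("gene")["true_log2fc"]
    sign_ok = [
        np.sign(tab.loc[g, "log2fc"]) == np.sign(truth_lfc[g]) for g in recovered
    ]
    return {
        "type1_rate": type1,
        "sensitivity": sensitivity,
        "sign_agreement": float(np.mean(sign_ok)) if sign_ok else float("nan"),
        "n_null_genes": n_genes,
        "n_planted": len(planted),
    }
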