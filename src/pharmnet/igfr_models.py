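"""Packaged IGF-1R / ER-alpha network reconstructions, scenario runner and
qualitative untreated-vs-treated comparison."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib.resources import files

import yaml

from .errors import DomainError
from .hybrid_petri_net import HybridPetriNet, Trajectory, fold_change, simulate

#: Simulation horizons used by the packaged scenarios (time units).
SCENARIO_HORIZONS = (10.0, 50.0, 100.0)

#: Horizon used for headline summaries (middle of the packaged three).
HEADLINE_HORIZON = 50.0

#: Proteins of the qualitative comparison table.
TABLE_PROTEINS = ("IGF1R", "IRS1", "ERalpha")

#: Optional additional rows supported by the packaged nets.
EXTRA_PROTEINS = ("p53", "BRCA1", "Mdm2", "Akt", "PI3k")

SYMBOL_UP_STRONG = "+++"
SYMBOL_UP_MODERATE = "++"
SYMBOL_DOWN = "---"
SYMBOL_INTERMEDIATE = "±"


def _load_net(resource: str) -> HybridPetriNet:
    text = files("pharmnet").joinpath(f"models/{resource}").read_text()
    return HybridPetriNet.from_dict(yaml.safe_load(text))


def build_untreated() -> HybridPetriNet:
    """The untreated (diseased) network: IGF-driven cascade with the
    ER-alpha -> IGF-1R positive feedback and ER-alpha-suppressed TSGs."""
    return _load_net("igf1r_untreated.yaml")


def build_treated() -> HybridPetriNet:
    """The fulvestrant-treated network: untreated net plus the inhibitor
    (a constant boundary place) and the PTEN arm."""
    return _load_net("igf1r_treated.yaml")


def run_scenarios(
    net: HybridPetriNet,
    horizons=SCENARIO_HORIZONS,
    **simulate_options,
) -> dict:
    """One deterministic trajectory per horizon (default 10/50/100)."""
    return {h: simulate(net, horizon=h, **simulate_options) for h in horizons}


# ---------------------------------------------------------------------------
# qualitative comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProfileThresholds:
    """Discretization bands for fold changes (frozen defaults).

    fold >= high        -> '+++'
    mid <= fold < high  -> '++'
    fold <= low         -> '---'
    otherwise           -> '±' (reported numerically with a warning)
    """

    high: float = 2.0
    mid: float = 1.2
    low: float = 0.5


@dataclass
class QualitativeTable:
    rows: dict  # protein -> {"untreated": symbol, "treated": symbol, ...folds}
    thresholds: ProfileThresholds = field(default_factory=ProfileThresholds)

    def symbol(self, protein: str, condition: str) -> str:
        return self.rows[protein][condition]

    def to_dataframe(self):
        import pandas as pd

        records = []
        for protein, cells in self.rows.items():
            records.append(
                {
                    "protein": protein,
                    "untreated": cells["untreated"],
                    "treated": cells["treated"],
                    "untreated_fold": cells["untreated_fold"],
                    "treated_fold": cells["treated_fold"],
                }
            )
        return pd.DataFrame(records)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _discretize(fold, thresholds: ProfileThresholds, protein: str, condition: str) -> str:
    if fold is None:
        warnings.warn(
            f"{protein}/{condition}: fold change undefined (zero initial marking)"
        )
        return SYMBOL_INTERMEDIATE
    if fold >= thresholds.high:
        return SYMBOL_UP_STRONG
    if fold >= thresholds.mid:
        return SYMBOL_UP_MODERATE
    if fold <= thresholds.low:
        return SYMBOL_DOWN
    warnings.warn(
        f"{protein}/{condition}: fold change {fold:.3f} falls in no band; "
        f"reported as intermediate"
    )
    return SYMBOL_INTERMEDIATE


def qualitative_profile(
    untreated: Trajectory,
    treated: Trajectory,
    proteins=TABLE_PROTEINS,
    thresholds: ProfileThresholds = ProfileThresholds(),
    mode: str = "final_over_initial",
) -> QualitativeTable:
    """Discretized per-protein fold changes for both conditions.

    Fold changes default to final-over-initial: a peak-based ratio is
    bounded below by 1 (the initial point is on the grid) and therefore
    cannot express down-regulation.
    """
    for traj, cond in ((untreated, "untreated"), (treated, "treated")):
        missing = [p for p in proteins if p not in traj.place_names]
        if missing:
            raise DomainError(f"{cond} trajectory lacks place(s): {missing}")
    rows = {}
    for protein in proteins:
        uf = fold_change(untreated, protein, mode)
        tf = fold_change(treated, protein, mode)
        rows[protein] = {
            "untreated": _discretize(uf, thresholds, protein, "untreated"),
            "treated": _discretize(tf, thresholds, protein, "treated"),
            "untreated_fold": uf,
            "treated_fold": tf,
        }
    return QualitativeTable(rows=rows, thresholds=thresholds)


def compare_conditions(
    horizon: float = HEADLINE_HORIZON,
    proteins=TABLE_PROTEINS,
    thresholds: ProfileThresholds = ProfileThresholds(),
    **simulate_options,
):
    """Simulate both packaged nets and build the qualitative table."""
    untreated = simulate(build_untreated(), horizon, **simulate_options)
    treated = simulate(build_treated(), horizon, **simulate_options)
    table = qualitative_profile(untreated, treated, proteins, thresholds)
    return untreated, treated, table


def plot_comparison(untreated: Trajectory, treated: Trajectory, out_dir, proteins=None):
    """Per-protein untreated-vs-treated panels (one PNG per protein)."""
    from pathlib import Path

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    proteins = proteins or [
        p for p in untreated.place_names if p in treated.place_names and p != "IGF"
    ]
    written = []
    for protein in proteins:
        fig, ax = plt.subplots(figsize=(4.5, 3))
        ax.plot(untreated.times, untreated.marking(protein), "k-", label="untreated")
        ax.plot(treated.times, treated.marking(protein), "g-", label="treated")
        ax.set_title(protein)
        ax.set_xlabel("time")
        ax.set_ylabel("marking")
        ax.legend(fontsize=8)
        fig.tight_layout()
        path = out_dir / f"compare_{protein}.png"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        written.append(path)
    return written
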