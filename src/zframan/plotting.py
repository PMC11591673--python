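"""Plain heatmap export of a fingerprint table (no styling contract)."""

from __future__ import annotations

from pathlib import Path

from .pls import FingerprintTable


def fingerprint_heatmap(table: FingerprintTable, path: str | Path) -> None:
    """Save a simple two-panel heatmap: modules bar + stage x descriptor
    projections, descriptors ordered by descending module."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = list(table.modules.index)
    S = table.projections[order]
    fig, (ax0, ax1) = plt.subplots(
        1, 2, figsize=(2 + 0.5, 0.35 * len(order) + 1.5),
        gridspec_kw={"width_ratios": [1, max(2, S.shape[0])]},
        constrained_layout=True,
    )
    ax0.barh(range(len(order)), table.modules[order], color="steelblue")
    ax0.set_yticks(range(len(order)), order, fontsize=7)
    ax0.invert_yaxis()
    ax0.set_xlabel("module")
    vmax = float(abs(S.to_numpy()).max()) or 1.0
    im = ax1.imshow(S.T.to_numpy(), aspect="auto", cmap="RdYlGn_r", vmin=-vmax, vmax=vmax)
    ax1.set_xticks(range(S.shape[0]), [str(c) for c in S.index], fontsize=7)
    ax1.set_yticks([])
    ax1.set_xlabel("stage (hpf)")
    fig.colorbar(im, ax=ax1, label="scalar projection")
    fig.suptitle(table.organ or "fingerprint")
    fig.savefig(path, dpi=120)
    plt.close(fig)
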