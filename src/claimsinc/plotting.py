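"""Benchmark bar chart: claims-based ACI per algorithm vs the registry value."""
from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def benchmark_bar(results, registry, site: str, ax=None):
    """Bars of claims ACI per algorithm with the registry ACI as a line.

    ``results`` is a fitted ``ClaimsIncidenceResults``; ``registry`` a
    (site, sex, state, aci) table with an ALL/ALL national row per site.
    """
    site = site.upper()
    ov = results.results
    sub = ov[(ov["site"] == site) & (ov["stratum_type"] == "overall")]
    reg = registry[
        (registry["site"] == site)
        & (registry["state"] == "ALL")
        & (registry["sex"].isin(["ALL", "F", "M"]))
    ]
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    ax.bar(sub["algorithm_label"], sub["aci"], color="#4878a8")
    if not reg.empty:
        ref = float(reg.iloc[-1]["aci"])
        ax.axhline(ref, color="#c44e52", linestyle="--", label=f"registry ({ref:.1f})")
        ax.legend()
    ax.set_ylabel("ACI per 100,000")
    ax.set_title(f"{site.title()} cancer: claims-based ACI by algorithm")
    ax.tick_params(axis="x", rotation=60)
    ax.figure.tight_layout()
    return ax
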