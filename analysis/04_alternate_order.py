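#!/usr/bin/env python
"""Ordering sensitivity of the environmental effects.

Tidal covariates are themselves lunar-periodic, so the share of
settlement variance the environmental regression appears to explain
depends on where it enters the pipeline.  This driver fits the
environmental model to the raw log data, the seasonal residuals, the
seasonal+lunar residuals, and the fully whitened residuals, and
tabulates the explained share (relative to raw log-variance) at each
entry point.
"""

from pathlib import Path

from crabsettle import io
from crabsettle.decomposition import alternate_order_analysis

DATA = Path("results/simdata")
OUT = Path("results")


def main() -> None:
    moons = io.read_new_moons(DATA / "new_moons.csv")
    settlement = io.read_settlement_csv(DATA / "settlement.csv", moons)
    env = io.read_env_csv(DATA / "covariates.csv")

    tab = alternate_order_analysis(settlement, env)
    io.write_table(tab, OUT / "alternate_ordering.csv")
    print(tab.to_string(index=False,
                        float_format=lambda v: f"{v:.3f}"))
    m = tab[tab["site"] == "MEAN"].set_index("entry")["explained_share"]
    print(f"\nCross-site mean explained share: raw {100 * m['raw']:.1f}%, "
          f"after seasonal removal {100 * m['post_seasonal']:.1f}%, "
          f"after lunar removal {100 * m['post_lunar']:.1f}%, "
          f"after whitening {100 * m['post_arima']:.1f}%.")
    print("Apparent environmental power shrinks as the harmonic trends "
          "it shares with the tide are removed first.")


if __name__ == "__main__":
    main()
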