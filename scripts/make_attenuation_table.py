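"""Regenerate the derived material attenuation table and default library file.

The elemental mass-attenuation grid lives in ``pcammd.attenuation``
(total-with-coherent cm^2/g at 60/80/100/150 keV, NIST-style
tabulation).  This script materializes everything derived from it:

* the per-material HU vertices at the working 70/150 keV pair,
* ``src/pcammd/data/default_library.yaml`` (the shipped library file,
  kept byte-for-byte in sync with ``build_default_library()``).

Run from the repository root:

    python scripts/make_attenuation_table.py [--write]

Without ``--write`` it prints the table for auditing only.
"""

import argparse
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from pcammd import attenuation
from pcammd.materials import build_default_library, save_library


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--write", action="store_true",
                        help="rewrite src/pcammd/data/default_library.yaml")
    args = parser.parse_args()

    e_low, e_high = 70.0, 150.0
    print(f"# working energies: {e_low:.0f} / {e_high:.0f} keV")
    print(f"# mu_water: {attenuation.mu_water(e_low):.6f} / "
          f"{attenuation.mu_water(e_high):.6f} cm^-1")
    print(f"{'element':>8s} {'mu/rho@70':>12s} {'mu/rho@150':>12s}")
    for sym in attenuation.ELEMENT_MU_RHO:
        print(f"{sym:>8s} {attenuation.element_mu_rho(sym, e_low):12.6f} "
              f"{attenuation.element_mu_rho(sym, e_high):12.6f}")

    lib = build_default_library((e_low, e_high))
    print(f"\n{'material':>16s} {'HU@70':>10s} {'HU@150':>10s} {'ref mg/mL':>10s}")
    for m in lib.materials:
        ref = f"{m.reference_concentration:g}" if m.reference_concentration else "-"
        print(f"{m.name:>16s} {m.attenuation_low:10.2f} "
              f"{m.attenuation_high:10.2f} {ref:>10s}")

    if args.write:
        out = Path(__file__).resolve().parents[1] / "src" / "pcammd" / "data" / "default_library.yaml"
        save_library(lib, out)
        print(f"\nwrote {out}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
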