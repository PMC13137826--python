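"""Mixing-model arithmetic for the laminar co-flow chip.

Computes, from the chip geometry (100 x 100 um channel, 87 mm long, 14
ul/min total flow) and infinite-dilution diffusion coefficients, the Fick
diffusion time of each metal ion across the 50 um half-channel, the axial
distance the flow covers in that time, and the dilution plateau of the
protein stream. Writes results/mixing.csv.

Expected outcome: ions equilibrate in ~1.7-1.9 s (~40 mm downstream), well
inside the 3.64 s / 87 mm observation window, and the protein signal
plateaus at 1/3 of its initial value (equal-thirds flow split).
"""

import argparse
from pathlib import Path

from trsaxs.mixing import MixingGeometry, dilution_plateau, mixing_report


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", default="results", type=Path)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    geom = MixingGeometry()
    positions = [5.0, 10.0, 20.0, 40.0, 60.0, 87.0]
    table = mixing_report(geom, positions_mm=positions)
    table.to_csv(args.out / "mixing.csv", index=False)

    print(f"mean axial velocity: {geom.mean_velocity_mm_s:.2f} mm/s")
    for _, row in table[table["kind"] == "diffusion"].iterrows():
        print(f"  {row['label']:>2}: t_D = {row['time_s']:.2f} s "
              f"-> {row['axial_distance_mm']:.1f} mm downstream")
    print(f"full-channel residence time: {table[table['label'] == '87mm']['time_s'].iloc[0]:.2f} s")
    print(f"dilution plateau (equal thirds, center inlet): "
          f"{dilution_plateau(geom, 1):.3f}")
    print(f"wrote {args.out / 'mixing.csv'}")


if __name__ == "__main__":
    main()
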