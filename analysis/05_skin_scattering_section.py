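"""Ballistic vs diffusive transport through the skin layer.

Renders the fluence cross-section perpendicular to the imaging plane for a
steep 60-deg beam through human-thickness (2 mm) skin, at the nominal skin
scattering and with the skin scattering coefficient cut by a factor of 10.
With full scattering the beam loses its directionality inside the layer
(diffusive transport); with reduced scattering the tilted ballistic beam
survives and delivers more light to the imaging plane.

Writes results/sections/section_scale{1,0.1}.png and a small summary table.

Usage: python analysis/05_skin_scattering_section.py [--photons N] [--pitch P] [--seed S]
"""

import argparse
import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from palight.optics_db import TissueSpec
from palight.sweeps import StudyPlan, fluence_section


def main():
    logging.basicConfig(level=logging.INFO, format="%(asctime)s %(message)s")
    ap = argparse.ArgumentParser()
    ap.add_argument("--photons", type=int, default=1_000_000)
    ap.add_argument("--pitch", type=float, default=0.15)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", default="results/sections")
    args = ap.parse_args()
    out = Path(args.outdir)
    out.mkdir(parents=True, exist_ok=True)
    plan = StudyPlan(voxel_pitch=args.pitch, n_photons=args.photons,
                     master_seed=args.seed)
    tissue = TissueSpec("fibrous", 700)
    rows = []
    for scale in (1.0, 0.1):
        sec = fluence_section(tissue, 2.0, 60.0, plan, skin_mu_s_scale=scale)
        rows.append({"mu_s_scale": scale, "peak": sec["peak"],
                     "peak_depth_mm": sec["peak_depth_mm"]})
        fig, ax = plt.subplots(figsize=(5, 4))
        with np.errstate(divide="ignore"):
            img = np.log10(np.where(sec["section"] > 0, sec["section"], np.nan))
        left, right, bottom, top = sec["extent_mm"]
        im = ax.imshow(img.T, extent=(left, right, bottom, top),
                       origin="upper", vmin=np.nanmax(img) - 4)
        ax.set_xlabel("lateral offset x (mm)")
        ax.set_ylabel("depth z (mm)")
        ax.set_title(f"60-deg beam, 2 mm skin, mu_s x{scale:g}")
        fig.colorbar(im, label="log10 fluence (1/mm$^2$)")
        fig.tight_layout()
        fig.savefig(out / f"section_scale{scale:g}.png", dpi=150)
        plt.close(fig)
    df = pd.DataFrame(rows)
    df.to_csv(out / "section_peaks.tsv", sep="\t", index=False)
    print(df.to_string(index=False))
    gain = df.peak.iloc[1] / df.peak.iloc[0]
    print(f"\nCutting skin scattering 10x raises the imaging-plane peak "
          f"{gain:.2f}x: the tilted beam stays ballistic through the layer.")


if __name__ == "__main__":
    main()
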