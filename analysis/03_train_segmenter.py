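"""Train the lobe segmentation network on a synthetic cohort.

Ten volunteers (20 lobes) are simulated, the first observer's sweeps are
compounded and preprocessed to 64×64 axial slices, and the network is
trained with the study recipe (combined Dice + cross-entropy loss, equal
weights, edge weights, dropout 0.5, batch 4, ≤20 epochs with early
stopping).  Writes the training report and a checkpoint under results/.
"""

import json
import sys
import time
from pathlib import Path

from thyrus.acquisition import AcquisitionParams
from thyrus.io import RunConfig
from thyrus.nn.network import save_network
from thyrus.pipeline import train_study_model
from thyrus.study import generate_study

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path("results")
OUT.mkdir(exist_ok=True)

cfg = RunConfig(seed=SEED, n_volunteers=10, n_repeats=1)
acq = AcquisitionParams.desk(image_px=cfg.image_px, pixel_mm=cfg.pixel_mm,
                             frame_rate=cfg.frame_rate)
t0 = time.time()
study = generate_study(n_volunteers=cfg.n_volunteers, n_repeats=1, seed=SEED, acquisition=acq)
model, report, info = train_study_model(study, cfg)
elapsed = time.time() - t0

save_network(model, OUT / "segmenter.npz", seed=SEED)
payload = {**report.to_dict(),
           "train_volunteers": info["train_volunteers"],
           "val_volunteers": info["val_volunteers"],
           "elapsed_s": round(elapsed, 1)}
(OUT / "train_report.json").write_text(json.dumps(payload, indent=2))

print(f"trained on {2*len(info['train_volunteers'])} lobes, validated on "
      f"{2*len(info['val_volunteers'])} ({elapsed/60:.1f} min)")
print(f"best validation Dice {report.best_val_dice:.4f} at epoch {report.best_epoch} "
      f"of {report.epochs_run}")
print(f"wrote {OUT/'segmenter.npz'} and {OUT/'train_report.json'}")
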