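# odcseg

Shape-constrained unsupervised domain adaptation for joint **optic disc and
cup segmentation** in retinal fundus images.

Glaucoma screening hinges on the vertical cup-to-disc ratio (CDR), which
requires segmenting the optic disc (OD) and the optic cup (OC).  Networks
trained on one camera/dataset degrade on another, and adversarial domain
adaptation often produces ragged, anatomically implausible regions.  This
package implements a domain-adaptation framework whose core is a
**differentiable circularity prior**: both structures are close to circles
in every dataset, so the spread of contour-to-centroid distances is a
domain-invariant penalty on malformed predictions.

For a contour with points `p_i`, centroid `c`, radial distances
`E_i = |p_i − c|` and mean distance `m`:

    L_region = (1/k) Σ_i (E_i − m)² / m²,      L_shape = L_disc + L_cup

`L_shape` is zero exactly for circles, scale- and translation-invariant,
and strictly increasing in ellipse eccentricity.  During training it is
evaluated in a differentiable form on soft probability maps (boundary
weights `p − minpool₃ₓ₃(p)`), summed over the segmentations of the source
image, the target image and both cross-domain translations.

Around this prior the framework couples

* a **content/style translation model** (shared content encoder, style
  encoder, decoder, two patch discriminators) aligning the two domains in
  input space, and
* a **U-Net segmenter with triple attention (CTAM)** reading the shared
  content features, adversarially aligned in output space by a
  discriminator on segmentation probability maps.

Everything runs on a small numpy autodiff backend (`odcseg.nn`) — no GPU
framework required.  Because the real cross-domain benchmarks need
full-scale GPU training, the package ships a **two-domain synthetic fundus
phantom generator** with known ground truth, so the whole pipeline is
testable end to end on a CPU.

## Worked example

```python
import numpy as np
from odcseg import (PhantomSpec, generate_phantom, shape_loss_hard,
                    vertical_cdr)

# a jitter-free phantom: disc and cup are rasterized circles
img, mask = generate_phantom(PhantomSpec(image_size=128, boundary_jitter=0.0,
                                         seed=3))
v = shape_loss_hard(mask)
print(f"cup={float(v.cup_term):.5f} disc={float(v.disc_term):.5f} "
      f"total={float(v.total):.5f}")
print(f"CDR={vertical_cdr(mask):.3f}")

# squash everything vertically by 2x: both terms jump
print(f"squashed total={float(shape_loss_hard(mask[::2]).total):.4f}")
```

prints

```
cup=0.00073 disc=0.00013 total=0.00086
CDR=0.420
squashed total=0.1091
```

Near-zero loss for circles (the residual is rasterization noise), a
hundred-fold jump once the structures become 2:1 ellipses, and a CDR read
off the generated mask.  Training end to end:

```bash
odcseg --seed 0 --out-dir data synth --n-per-domain 30 --image-size 64
odcseg --seed 0 --out-dir run train data/manifest.csv --epochs 20 \
       --image-size 64
odcseg --out-dir run evaluate run/checkpoint.npz data/manifest.csv \
       --image-size 64
```

The `evaluate` command prints mean IoU/Dice for disc and cup on the
held-out target-domain split, and `run/training_log.csv` logs every loss
term per iteration (the `L_shape_*` columns track the circularity of the
four segmentation outputs).  `odcseg ablate` sweeps the shape-constraint
weight ρ₂ over 0.2–2.0 and tabulates the four metrics per weight;
`odcseg shape-loss mask.png` scores any label-map PNG.

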