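# dxt — a diffraction experiment toolbox

Processing single-crystal X-ray diffraction data requires an accurate model
of the experimental geometry, recovered losslessly from whatever file
format a beamline happens to write.  `dxt` separates the *interpretation*
of diffraction images from their *analysis*: an extensible plugin registry
of format classes reads image files (SMV-style text-header images, HDF5
multi-image containers) and maps their metadata onto a single standardized,
fully vectorial description of the experiment, so that analysis code never
needs to know about file formats or local beamline conventions.

It is aimed at developers of diffraction data-processing and visualization
software, and at beamline scientists who need to describe an idiosyncratic
instrument (a left-handed rotation axis, a detector on a 2θ arm) by adding
a single small Python file rather than patching analysis code.

## The models

Four container classes capture the separable parts of the experiment, all
expressed in a right-handed laboratory frame whose origin is the
intersection of the primary beam and the sample:

* **Beam** — unit propagation direction $\hat{s}$ (source → sample) and
  wavelength $\lambda$ (Å); the incident wavevector is
  $\mathbf{s}_0 = \hat{s}/\lambda$.
* **Goniometer** — a single arbitrary unit rotation axis $\hat{e}$ with
  right-handed sense; the axis is *not* assumed orthogonal to the beam.
* **Detector** — an ordered container of rectangular **panels**, not
  necessarily coplanar, optionally organized in a hierarchy of panel
  groups.  Each panel $k$ carries the matrix

  $$d_k = \begin{pmatrix} \mathbf{f}_k & \mathbf{s}_k & \mathbf{o}_k \end{pmatrix},$$

  whose columns are the unit fast axis, unit slow axis and origin vector
  (mm, lab frame) of the panel.  $d_k$ maps panel coordinates
  $(x, y, 1)^T$ to laboratory positions, and its inverse projects a
  scattered ray $\mathbf{s}$ onto the panel with pure matrix algebra — no
  trigonometry: $v = d_k^{-1}\mathbf{s}$ intersects at
  $(v_1/v_3,\, v_2/v_3)$ when $v_3 > 0$.
* **Scan** — the mapping between 1-based image numbers and rotation angle:
  $\varphi(i, f) = \varphi_0 + (i - i_0 + f)\,\Delta\varphi$; a still has
  $\Delta\varphi = 0$.

A position on the detector is a **virtual-plane coordinate**: panel id
plus millimetres on the front sensor surface.  The hardware-specific
mapping to pixels is an interchangeable strategy per panel: a simple
divide-by-pixel-size, or a **parallax-corrected** mapping for thick
sensors in which a photon entering at angle θ to the panel normal
traverses $T = t_0/\cos\theta$ of sensor and converts at mean depth
$\bar{t} = 1/\mu - T e^{-\mu T}/(1 - e^{-\mu T})$ along the ray,
displacing the recorded centroid by $\bar{t}$ times the in-plane ray
component.

Images are grouped by a datablock factory: one **DataBlock** per format
class, containing **ImageSweeps** (contiguous rotation series sharing one
beam/detector/goniometer and a single merged scan) and **ImageSets**
(stills and unmergeable images).  Sweeps and their subsets are flyweight
views over one shared reader.  Models and datablocks serialize losslessly
to JSON.

## Worked example

Generate a synthetic 3-image sweep (400×400 px panel of 0.1 mm pixels at
150 mm, λ = 0.9795 Å, 0.5°/image, two injected spots on a Poisson
background), then resolve, import and re-print it:

```sh
$ cat spec.json
{"n_images": 3, "spots": [{"ray": [0.0, 0.0, 1.0], "counts": 5000.0},
                          {"ray": [0.05, 0.02, 0.998], "counts": 5000.0}]}
$ dxt make-fixture --spec spec.json -o sweep
wrote 3 files under sweep
$ dxt show sweep/image_0001.img
sweep/image_0001.img: SMVADSC
  beam: direction (0, 0, 1), wavelength 0.9795 A
  goniometer: rotation axis (1, 0, 0)
  scan: images 1..1, start 0 deg, 0.5 deg/image
  detector: 1 panel(s)
    panel 0 'ADSC': 400x400 px of 0.1x0.1 mm, origin (-20, 20, 150), fast (1, 0, 0), slow (0, -1, 0)
$ dxt import sweep/image_000*.img -o datablock.json
wrote datablock.json
SMVADSC: 1 sweep(s), 0 set(s), 3 image(s)
$ dxt models datablock.json
datablock (SMVADSC)
sweep of 3 image(s):
  ...
  scan: images 1..3, start 0 deg, 0.5 deg/image
```

The file resolved to the plain ADSC dialect of the SMV family; the panel
origin (−20, 20, 150) mm places the direct beam at the header beam centre
(20, 20) mm; and the three single-image scans merged into one contiguous
1..3 sweep covering 0–1.5°.  Writing the same spec with
`--hdf5` produces a single container whose pixel stack is byte-identical
and which imports to the same sweep through the HDF5 format class.

Library use mirrors the CLI:

```python
from dxt import datablocks_from_files

block = datablocks_from_files(paths)[0]
sweep = block.sweeps()[0]
beam, detector = sweep.get_beam(), sweep.get_detector()
hit = detector.ray_intersect(s)          # (panel id, mm on the panel) or None
px = detector[hit.panel_id].mm_to_px(hit.xy)
```

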