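# fgaorta

A self-contained simulator of the biomechanics of natural and functionally
graded (FGM) artificial aortas: a thick-walled compliant vessel with a
radially graded linear-elastic wall, loaded by a reduced-order pulsatile
lumen-pressure model, solved by two independent discretizations
(differential quadrature and finite differences) with two-way partitioned
fluid–structure coupling.

## Quick start

Command line:

```bash
# paired-discretization benchmark with an error report (exit nonzero if any
# discrepancy exceeds its bound)
fgaorta validate --out validation_out

# two-way coupled aorta run; writes fields, coupling log, profiles
fgaorta fsi-run --solver dqm --out fsi_out

# heterogeneous-index sweep against a layered natural-vessel reference
fgaorta fgm-sweep --index 0.2 --index 1 --index 5 --out sweep_out
```

Python:

```python
import numpy as np
from fgaorta import aorta_scenario, couple
from fgaorta.fsi import aorta_flow
from fgaorta.postprocess import extract_profile

result = couple(aorta_scenario(method="dqm"), aorta_flow())
profile = extract_profile(result.solution, "s_tt", "time")  # mid-thickness hoop stress
print(profile.head())
```

## Modules

| module | contents |
| --- | --- |
| `fgaorta.materials` | constituent materials, power-law property fields, FGM grading law, layered natural wall |
| `fgaorta.hemodynamics` | inlet waveforms, Poiseuille gradient, thin-wall distension, axial pressure march |
| `fgaorta.dqm` | Chebyshev–Gauss–Lobatto nodes and differential-quadrature weighting matrices |
| `fgaorta.structural` | axisymmetric elastodynamic wall solver (DQM and FD discretizations, Newmark time stepping), Lamé closed form, validation experiment |
| `fgaorta.fsi` | partitioned two-way coupling with under-relaxed fixed-point iterations |
| `fgaorta.postprocess` | nondimensionalization, von Mises stress, 1D profile extraction, peak detection |
| `fgaorta.cli` | `fgaorta` command group, YAML scenario configs, run artifacts |

## Acceptance quantities

`scripts/acceptance.py` recomputes the package's cross-method agreement
numbers from scratch and writes them as JSON:

```bash
python scripts/acceptance.py --seed 1 --out acceptance_results.json
```

- `t1`–`t3`: DQM-vs-FD discrepancies on the graded-cylinder benchmark
  (radial displacement, hoop stress, axial stress; mid-thickness report
  line, all axial positions and times).
- `t5`/`t6`: grading-law modulus at the inner/outer surface in MPa
  (exact constituent values for every heterogeneous index).
- `t7`/`t8`: coupled-model cross-discretization discrepancies on the aorta
  scenario (mid-thickness hoop stress vs time; mid-thickness radial
  displacement vs length in the 2–3 s window).

All solves are deterministic; the full script runs in about a minute on one
CPU.

## Testing

```bash
python -m pytest
```

The suite includes unit tests per module, hypothesis property tests
(derandomized), and `tests/test_acceptance.py` with one test per acceptance
criterion. The complete run takes a few minutes; the coupled-model
comparison dominates the runtime.

See `docs/methods.md` for the governing equations, the two discretizations,
and the reasoning behind the numerical choices.
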