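# qtst

Rigid-rotor/harmonic-oscillator (RRHO) gas-phase partition functions,
machine-learned partition-function estimators, and transition-state-theory
(TST) rate constants that need no transition-state geometry search.

## The problem

Computing a reaction rate constant ab initio is dominated by finding the
transition state: locating a first-order saddle point typically takes orders
of magnitude more compute than anything that follows. Yet what TST actually
consumes is not the geometry itself but the partition functions,

    Q(T) = Q_el · Q_trans · Q_rot · Q_vib        (RRHO factorization)
    k(T) = (k_B T / h) · (Q_TS / Q_R) · e^(−E_a / k_B T)

This package provides both halves of a shortcut for unimolecular gas-phase
reactions of small organics (C/H/N/O):

* an **exact RRHO evaluator** — XYZ + harmonic frequencies in, ln Q and its
  four factor components out, including rotational symmetry-number
  detection with the linear-molecule exception (a perpendicular C₂ of a
  centrosymmetric linear molecule presents as an improper reflection and
  must still give σ = 2);
* three **learned estimators** — *Qest* (geometry + 1/T → ln Q), *QesTS*
  (reactant/product geometries + their ln Q + 1/T → ln Q_TS) and *Double*
  (their composition: reactant and product geometries only → ln Q_TS), with
  scaffold-grouped hold-out/fold splitting, encoded-bond 3D featurization,
  a temperature-only null baseline ln Q = m·(1/T) + b, and MAE reported as
  percent of the target standard deviation.

It is aimed at kinetics and reaction-network practitioners who want
partition functions and TST prefactors at interactive speed, and at anyone
studying how much of a transition state's thermochemistry is recoverable
from reactant and product information alone.

## Worked example

```python
from qtst import (read_xyz, rotational_symmetry_number, total_log_q,
                  tst_log_rate, ThermoState)

water = read_xyz("""3
water
O  0.000000  0.000000  0.117790
H  0.000000  0.755450 -0.471160
H  0.000000 -0.755450 -0.471160""").with_(
    frequencies=(1594.7, 3657.1, 3755.9), id="water")

sym = rotational_symmetry_number(water)
print(sym.sigma, sym.operations_found)   # 2 4   (C2v: E, C2, 2 sigma_v)

q = total_log_q(water, ThermoState(298.15))
print(f"{q.log_q_trans:.4f} {q.log_q_rot:.4f} {q.log_q_vib:.4f} {q.log_q_total:.4f}")
# 14.9291 3.7606 -21.7337 -3.0440
```

Reading the numbers: at 298 K water's translational factor is e^14.93 ≈ 3×10⁶
(1 bar volume convention), the rotational factor e^3.76 ≈ 43 is divided by
σ = 2, and ln Q_vib = −21.73 is negative because the zero-point energy is
kept inside Q_vib — its e^(−hcν/2k_BT) factors dominate the stiff O–H
modes. The total is the sum of the components by construction.

A barrier of 0.05 hartree with equal partition functions for reactant and
transition state gives

```python
rate = tst_log_rate(q.log_q_total, q.log_q_total, 0.05, ThermoState(298.15),
                    ea_unit="hartree")
print(f"{rate.log_k:.3f}")   # -23.498  (ln k, k in s^-1)
```

i.e. k = e^(29.458) · e^(−52.956) ≈ 6×10⁻¹¹ s⁻¹: the universal attempt
frequency k_BT/h ≈ 6.2×10¹² s⁻¹ multiplied by a 31 kcal/mol Boltzmann
penalty. Note the rate depends only on the *difference* of the two ln Q
inputs, so the translational volume convention cancels.

There is also a CLI for file-based workflows:

```bash
qtst make-fixtures --n-reactions 50 --n-temps 10 --seed 0 --out reactions.json
qtst compute-q  --reactions reactions.json --out q.csv
qtst tst-rate   --reactions reactions.json --reaction-id rxn00000 --out rates.csv
qtst train      --reactions reactions.json --model qest --out qest_bundle/
```

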