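# Incidence-based Hill numbers: formula sheet

Notation. `T` sampling units (stations) in one group; incidence
frequencies `Y_i` = number of units where cluster `i` was detected
(`1 ≤ Y_i ≤ T`); `S_obs` observed clusters; `U = Σ Y_i` total incidences;
`Q1`, `Q2` = number of clusters detected in exactly one / two units.

## Observed diversities (t = T)

With `p_i = Y_i / U`:

* `⁰D = S_obs`
* `¹D = exp(−Σ p_i ln p_i)`
* `²D = 1 / Σ p_i²`

## Interpolation (t ≤ T)

Subsampling `t` of `T` units without replacement gives hypergeometric
detection counts. With `Q_k(t) = Σ_i C(Y_i, k) C(T−Y_i, t−k) / C(T, t)`
(the expected number of clusters detected in exactly `k` of the `t`
units) and `U_t = t·U/T`:

* `⁰D(t) = S_obs − Σ_i C(T−Y_i, t) / C(T, t)`
* `¹D(t) = exp(−Σ_{k≥1} (k/U_t) ln(k/U_t) · Q_k(t))`
* `²D(t) = U_t² / Σ_i E[Y'_i²]`, where `Y'_i` is hypergeometric with
  mean `tY_i/T` and variance `(tY_i/T)(1−Y_i/T)(T−t)/(T−1)`

All three are exact expectations; at `t = T` they reduce to the observed
values, and the q = 0 form is verified against a subsampling Monte-Carlo
oracle in the tests.

## Asymptotes

* `⁰D(∞)` — Chao2:
  `S_obs + ((T−1)/T)·Q1²/(2Q2)` when `Q2 > 0`, else
  `S_obs + ((T−1)/T)·Q1(Q1−1)/2`.
* `¹D(∞)` — exponential of the incidence entropy estimator: with
  `A = 2Q2 / ((T−1)Q1 + 2Q2)` (or `2/((T−1)(Q1−1)+2)` when `Q2 = 0`,
  `Q1 > 1`),

  ```
  Ĥ_raw = Σ_{Y_i ≤ T−1} (Y_i/T) Σ_{k=Y_i}^{T−1} 1/k
        + (Q1/T)(1−A)^{1−T} [−ln A − Σ_{r=1}^{T−1} (1−A)^r / r]
  ¹D(∞) = exp( (T/U)·Ĥ_raw + ln(U/T) )
  ```

* `²D(∞)` — bias-corrected inverse Simpson:
  `((T−1)/T) · U² / Σ_i Y_i(Y_i − 1)`.

Harmonization: the three asymptotes are estimated independently and
need not satisfy the Hill inequality jointly, so `¹D(∞)` is clipped into
`[¹D_obs, ⁰D(∞)]` and `²D(∞)` into `[²D_obs, ¹D(∞)]`. When `Q1 = 0`
(no uniques, hence no evidence of undetected clusters) all three
asymptotes are the observed values — the same convention Chao2 itself
follows.

## Extrapolation (t = T + t*)

* `⁰D(T+t*) = S_obs + Q̂0 [1 − (1 − Q1/(Q1 + T·Q̂0))^{t*}]`, with `Q̂0`
  the Chao2 correction term.
* `¹D(T+t*) = exp( (T/(T+t*))·ln ¹D_obs + (t*/(T+t*))·ln ¹D(∞) )`,
  a monotone entropy interpolation between the observed value and the
  asymptote.
* `²D(T+t*) = 1 / [ T/(tU) + ((t−1)/t) · Σ Y_i(Y_i−1) / (U²(T−1)/T) ]`
  with `t = T+t*` — the closed form is valid at any effort, passes
  through `²D_obs` at `t = T` and increases towards `²D(∞)`.

Each extrapolated value is additionally capped by the next-lower order's
value at the same effort, so the reported profile always satisfies
`⁰D(t) ≥ ¹D(t) ≥ ²D(t)`; with `Q1 = 0` the extrapolations stay flat at
the observed values. The default grid spans `1..2T` (the conventional
reliability limit for extrapolation; configurable).
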