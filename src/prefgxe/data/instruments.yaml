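# Default instrument battery: six-lottery risk-elicitation menus and two
# multiple-price-list (MPL) discounting panels.  Payoffs in GBP; MPL delays in
# weeks (the effective delay between the sooner and the future payment date).
beg_menu:
  name: beg
  labels: [A, B, C, D, E, F]
  lotteries:
    - {low: 28, high: 28}
    - {low: 24, high: 36}
    - {low: 20, high: 44}
    - {low: 16, high: 52}
    - {low: 12, high: 60}
    - {low: 2, high: 70}
la_menu:
  name: loss_aversion
  labels: [A, B, C, D, E, F]
  lotteries:
    - {low: 10, high: 10}
    - {low: 6, high: 18}
    - {low: 2, high: 22}
    - {low: -2, high: 28}
    - {low: -4, high: 35}
    - {low: -5, high: 38}
mpl_panels:
  one_month:
    sooner_amount: 25
    future_amounts: [26, 28, 30, 32, 35, 38]
    delay_weeks: 2.43
  two_month:
    sooner_amount: 25
    future_amounts: [26, 30, 35, 37, 40, 45]
    delay_weeks: 6.71
planning_horizon_levels:
  - does not plan/plans day to day
  - the next few weeks
  - the next few months
  - the next year
  - the next few years
  - the next 5-10 years
  - longer than 10 years
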