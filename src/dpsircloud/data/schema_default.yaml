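# Default DPSIR indicator schema and five-grade scheme for ecological
# restoration project assessment. 14 indicators: 7 positive, 4 negative,
# 3 neutral.
indicators:
  - {code: D1, category: D, attribute: positive, description: Economic development}
  - {code: D2, category: D, attribute: negative, description: Population size}
  - {code: P1, category: P, attribute: negative, description: Construction development intensity}
  - {code: P2, category: P, attribute: negative, description: Damage intensity of the original environment}
  - {code: P3, category: P, attribute: negative, description: Pollution intensity during the operation period}
  - {code: S1, category: S, attribute: positive, description: Expected improvement of ecological restoration}
  - {code: S2, category: S, attribute: positive, description: Improvement of tourism resources}
  - {code: S3, category: S, attribute: positive, description: Pollution caused by human activities during operation}
  - {code: I1, category: I, attribute: positive, description: Economic benefits of land appreciation}
  - {code: I2, category: I, attribute: positive, description: Environmental benefits}
  - {code: I3, category: I, attribute: positive, description: Social benefits}
  - {code: R1, category: R, attribute: neutral, description: Project investment}
  - {code: R2, category: R, attribute: neutral, description: Degree of control over pollution and damage during construction}
  - {code: R3, category: R, attribute: neutral, description: Participation and management level during operation}
grades:
  - {label: I, lower: 0.0, upper: 0.2, description: small}
  - {label: II, lower: 0.2, upper: 0.4, description: little}
  - {label: III, lower: 0.4, upper: 0.6, description: medium}
  - {label: IV, lower: 0.6, upper: 0.8, description: relatively great}
  - {label: V, lower: 0.8, upper: 1.0, description: great}
hyper_entropy_constant: 0.01
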