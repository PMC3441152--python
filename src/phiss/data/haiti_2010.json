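{
  "schema_version": "1.0",
  "assessment": {
    "site_id": "haiti-2010-earthquake",
    "assessed_at": "2010-02-12",
    "period_days": 30,
    "excess_deaths_count": 222570,
    "injury_cases": 300000,
    "healthcare_level": 4
  }
}
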