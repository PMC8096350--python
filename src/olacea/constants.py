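"""Model-wide constants and time-unit conversions.

All time-unit conversions go through this single table so that the
21-day cycle, the months-based survival curves and the annual discount
rate cannot drift apart across modules.
"""

DAYS_PER_YEAR: float = 365.0
DAYS_PER_MONTH: float = 30.4375  # 365.25 / 12, the Gregorian mean month

CYCLE_LENGTH_DAYS: float = 21.0
CYCLE_LENGTH_MONTHS: float = CYCLE_LENGTH_DAYS / DAYS_PER_MONTH
CYCLE_LENGTH_YEARS: float = CYCLE_LENGTH_DAYS / DAYS_PER_YEAR

HORIZON_YEARS: float = 5.0
DISCOUNT_RATE_ANNUAL: float = 0.05

#: 2020 CNY/USD exchange rate used for all currency conversion.
YUAN_PER_USD: float = 6.8985

#: Fixed US willingness-to-pay threshold, $/QALY.
US_WTP_USD_PER_QALY: float = 50_000.0

#: China 2019 GDP per capita (yuan); the Chinese WTP threshold is 3x this,
#: converted to USD.
CHINA_GDP_PER_CAPITA_YUAN: float = 70_892.0


def months_to_years(t_months: float) -> float:
    return t_months * DAYS_PER_MONTH / DAYS_PER_YEAR


def years_to_months(t_years: float) -> float:
    return t_years * DAYS_PER_YEAR / DAYS_PER_MONTH
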