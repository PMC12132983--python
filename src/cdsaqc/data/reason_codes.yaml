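# Reason codes for skipped or insufficient-quality sign assessments,
# as collected during structured observation of routine consultations.
forgot: Forgot to measure the sign
checked_hot_only: Only checked if the child was hot or not
no_thermometer: Did not bring or ask for the thermometer
thermometer_distance: Inadequate distance between child's skin and infrared thermometer
thermometer_location: Inadequate location of the thermometer
reading_too_early: Did not wait enough time before reading result
not_necessary: Did not consider the sign necessary to assess based on the child's symptoms
child_too_old: Considered the child to be too old (>5 years)
copied_health_card: Copied the result from a previous consultation in the child's health card
reused_previous_day: Used the result of the same sign already measured the day before
child_agitated: Child too agitated
ribbon_location: Inadequate location of the ribbon (not at mid-arm distance)
child_too_young: Child too young (<6 months)
ribbon_too_tight: Ribbon placed too tightly
ribbon_over_clothes: Ribbon placed over the child's clothes
ribbon_too_loose: Ribbon placed too loosely
heavily_dressed: Child too heavily dressed when weighed
wearing_shoes: Child wearing shoes when weighed
partially_supported: Child not weighing all that much on the scale because supported
balance_not_calibrated: Balance not calibrated
holding_objects: Child holding objects when weighed
no_meter: No meter available or meter considered as inadequate
estimated_visually: Sign estimated visually without measuring
agitated_or_injured: Child too agitated or with an injured leg
shoes_or_hat: Child wearing shoes or hat
not_touching_board: Heels or shoulder or head not touching the flat surface of the board
not_looking_straight: Child not looking straight forward
meter_not_straight: Meter not placed straight
bad_zero_or_meter: Did not start the measurement at 0 cm or used an inadequate meter
too_time_consuming: Sign considered as too time consuming
oximeter_broken: Oximeter out of function (no battery)
urgent_referral: Child requiring immediate referral to hospital because severely ill
probe_size_unavailable: Oximeter probe adequate for the age not available
probe_position: Inadequate position of the oximeter probe
no_timer_or_app: No timer or timing app available
used_oximeter: Directly used the pulse oximeter
underestimation: Underestimation
abdomen_covered: Did not uncover the abdomen
forgot_value: Forgot the value after finishing to count
not_full_minute: Did not measure over a full minute
timer_not_reset: Did not reset the timer before starting to count
overestimation: Overestimation
child_standing: Child standing instead of sitting or lying down
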