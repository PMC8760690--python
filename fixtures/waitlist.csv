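patient_id,recipient_age,blood_type,pra,medical_urgency,hla_a1,hla_a2,hla_b1,hla_b2,hla_dr1,hla_dr2,predicted_survival,diabetes,prior_solid_organ_transplant,dialysis_years,listing_date
P0001,29.8,AB,0.0,0,A5,A5,B3,B7,DR6,DR7,9.15,1,0,4.59,2016-08-16
P0002,62.7,A,0.0,0,A4,A7,B9,B7,DR1,DR6,6.98,0,0,3.45,2017-08-16
P0003,18.0,B,0.0,1,A9,A10,B6,B2,DR2,DR2,9.27,0,0,3.98,2017-01-16
P0004,20.0,A,0.0,0,A1,A7,B12,B4,DR1,DR5,16.62,0,0,2.08,2017-01-18
P0005,21.0,A,97.5,1,A7,A4,B11,B3,DR1,DR2,15.57,0,1,0.25,2017-04-14
P0006,42.2,B,20.6,0,A3,A7,B13,B3,DR8,DR4,6.76,1,0,12.03,2017-03-16
P0007,55.9,A,31.4,0,A6,A1,B1,B15,DR5,DR1,10.51,0,1,2.02,2016-01-25
P0008,34.3,A,89.2,0,A1,A1,B10,B2,DR4,DR2,9.99,0,0,1.81,2016-09-10
P0009,39.9,A,0.0,1,A10,A1,B2,B11,DR2,DR7,10.68,1,0,1.87,2008-01-02
P0010,63.7,A,30.4,0,A5,A5,B12,B7,DR8,DR8,5.59,0,0,0.52,2015-02-28
P0011,59.7,O,32.8,0,A6,A9,B1,B2,DR3,DR8,3.77,0,0,3.53,2016-08-04
P0012,40.1,B,0.0,1,A8,A10,B1,B3,DR5,DR7,9.14,0,0,3.93,2017-03-25
P0013,50.1,A,18.6,0,A6,A3,B2,B3,DR7,DR4,11.42,1,0,0.31,2017-07-08
P0014,56.9,O,21.6,0,A10,A1,B10,B4,DR7,DR3,8.18,0,0,1.33,2012-11-26
P0015,35.3,AB,0.0,0,A9,A7,B2,B6,DR5,DR5,12.5,0,0,3.73,2017-08-14
P0016,32.8,A,45.7,0,A10,A10,B8,B6,DR7,DR8,13.4,0,0,2.47,2017-09-02
P0017,35.4,O,42.6,0,A2,A6,B9,B8,DR1,DR3,6.59,0,0,12.25,2016-09-03
P0018,51.8,A,26.6,0,A1,A4,B5,B14,DR8,DR4,9.87,1,0,1.56,2017-11-05
P0019,47.1,O,9.7,0,A6,A2,B6,B11,DR1,DR3,12.16,0,0,0.86,2016-12-28
P0020,47.9,O,89.6,0,A1,A10,B8,B2,DR6,DR5,6.34,0,0,0.09,2017-12-09
P0021,33.2,O,0.0,0,A10,A4,B6,B8,DR2,DR2,14.49,0,0,0.56,2017-09-09
P0022,64.2,A,0.0,0,A5,A10,B8,B6,DR4,DR2,6.41,1,0,1.53,2014-06-28
P0023,31.9,B,0.0,1,A8,A3,B1,B15,DR5,DR7,5.31,0,0,5.64,2015-04-22
P0024,40.5,B,0.0,0,A5,A3,B10,B6,DR1,DR8,11.2,0,0,5.09,2016-05-12
P0025,33.4,A,0.0,0,A8,A6,B2,B1,DR5,DR3,13.65,1,1,3.86,2017-10-04
P0026,32.8,O,66.8,0,A5,A6,B10,B4,DR5,DR3,12.94,0,0,0.44,2017-06-18
P0027,73.8,A,0.0,0,A3,A4,B10,B11,DR8,DR5,9.26,0,0,0.25,2015-09-20
P0028,58.8,A,0.0,0,A7,A8,B11,B3,DR2,DR7,3.35,0,0,2.02,2017-01-28
P0029,66.9,O,0.0,0,A4,A3,B4,B13,DR6,DR8,7.47,0,0,0.05,2017-11-12
P0030,45.8,O,0.0,0,A10,A4,B2,B9,DR1,DR4,9.17,1,0,4.69,2017-01-01
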