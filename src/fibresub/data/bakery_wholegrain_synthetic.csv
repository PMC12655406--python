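sample_id,declared_category,assigned_category,has_seeds,outlet,fibre
B001,wholegrain,,False,small_bakery,2.4
B002,wholegrain,,True,small_bakery,2.8
B003,wholegrain,,False,small_bakery,3.1
B004,wholegrain,,True,small_bakery,3.3
B005,wholegrain,,False,small_bakery,3.4
B006,wholegrain,,False,small_bakery,3.5
B007,wholegrain,,True,small_bakery,3.6
B008,wholegrain,,True,small_bakery,3.7
B009,wholegrain,,False,small_bakery,3.9
B010,wholegrain,,True,small_bakery,4.0
B011,wholegrain,,False,small_bakery,4.1
B012,wholegrain,,True,small_bakery,4.3
B013,wholegrain,,True,small_bakery,4.4
B014,wholegrain,,False,small_bakery,4.5
B015,wholegrain,,True,small_bakery,4.6
B016,wholegrain,,False,small_bakery,4.7
B017,wholegrain,,True,small_bakery,4.8
B018,wholegrain,,True,small_bakery,4.9
B019,wholegrain,,False,small_bakery,5.0
B020,wholegrain,,True,small_bakery,5.0
B021,wholegrain,,True,small_bakery,5.1
B022,wholegrain,,False,small_bakery,5.1
B023,wholegrain,,True,small_bakery,5.2
B024,wholegrain,,True,small_bakery,5.2
B025,wholegrain,,False,small_bakery,5.2
B026,wholegrain,,True,small_bakery,5.2
B027,wholegrain,,False,small_bakery,6.2
B028,wholegrain,,True,small_bakery,7.2
B029,wholegrain,,True,small_bakery,8.0
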